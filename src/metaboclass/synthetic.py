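"""Seeded synthetic serum-metabolomics cohorts and spectral fixtures.

The generator emulates the statistical structure that the downstream
analysis assumes for GC-TOF-MS serum profiling of four autoimmune-disease
cohorts: 30 SLE patients in three severity phenotypes of 10, 20 primary
Sjögren's syndrome, 19 systemic sclerosis (9 limited + 10 diffuse
cutaneous) and 18 healthy volunteers; 243 putative metabolite features of
which 73 carry unique identifications, plus 11 stable-isotope-labeled
internal standards.

Peak areas follow a multiplicative log-normal model

    x_ij = f_i * b_j * exp(delta_{g(i), j}) * exp(eps_ij)

where ``f_i`` is a per-sample injection/ion-suppression efficiency factor
shared by every column (including internal standards), ``b_j`` a per-feature
baseline abundance, ``delta`` a log-scale group effect relative to the
healthy-volunteer baseline, and ``eps_ij`` measurement noise.  Internal
standards are spiked at fixed amounts and therefore carry no group effect.

The default effect specification plants the qualitative disease signatures
reported for these cohorts: exactly five identified metabolites up- and
fifteen down-shifted in SLE (tryptophan the strongest discriminator, down;
urea, uric acid and cystine up; arginine, ornithine, hypoxanthine, cysteine
and tyrosine down), a milder amino-acid depression in SSc with arginine
up, and several organic acids (fumaric acid among them) raised in pSS while
fumaric acid is lowered in SLE.  Magnitudes are stand-ins — the source
cohorts' per-metabolite fold-changes are not public — and are recorded as
such in the truth output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .identification import AlkaneSeries, MassSpectrum, SpectralLibraryEntry
from .tables import FeatureAnnotation, MetaboliteTable, SampleMetadata

__all__ = [
    "EffectSpec",
    "GeneratorConfig",
    "default_effectspec",
    "generate_cohort",
    "generate_spectral_fixtures",
]

# 26 amino acids (and amino-acid derivatives) detectable in derivatized serum
AMINO_ACIDS = (
    "alanine", "glycine", "serine", "threonine", "valine", "leucine",
    "isoleucine", "proline", "methionine", "phenylalanine", "tryptophan",
    "tyrosine", "arginine", "ornithine", "citrulline", "lysine", "histidine",
    "glutamic acid", "glutamine", "aspartic acid", "asparagine", "cysteine",
    "cystine", "taurine", "beta-alanine", "4-hydroxyproline",
)
ORGANIC_ACIDS = (
    "fumaric acid", "citric acid", "malic acid", "succinic acid",
    "2-oxoglutaric acid", "lactic acid", "pyruvic acid", "quinic acid",
    "hippuric acid", "3-hydroxybutyric acid", "oxalic acid", "glyceric acid",
)
FATTY_ACIDS = (
    "palmitic acid", "stearic acid", "oleic acid", "linoleic acid",
    "myristic acid", "arachidonic acid", "palmitoleic acid",
    "heptadecanoic acid",
)
PURINES = ("uric acid", "hypoxanthine", "xanthine", "inosine")
OTHER_IDENTIFIED = (
    "urea", "creatinine", "glucose", "fructose", "galactose", "myo-inositol",
    "glycerol", "cholesterol", "caffeine", "theobromine", "alpha-tocopherol",
    "uracil", "glycerol-3-phosphate", "threonic acid", "erythritol", "ribose",
    "sorbitol", "mannose", "sucrose", "maltose", "phosphoric acid",
    "pyroglutamic acid", "ethanolamine",
)

IDENTIFIED_METABOLITES: tuple = AMINO_ACIDS + ORGANIC_ACIDS + FATTY_ACIDS + PURINES + OTHER_IDENTIFIED
_CLASS_OF = {}
for _n in AMINO_ACIDS:
    _CLASS_OF[_n] = "amino_acid"
for _n in ORGANIC_ACIDS:
    _CLASS_OF[_n] = "organic_acid"
for _n in FATTY_ACIDS:
    _CLASS_OF[_n] = "fatty_acid"
for _n in PURINES:
    _CLASS_OF[_n] = "purine"
for _n in OTHER_IDENTIFIED:
    _CLASS_OF[_n] = "other"

INTERNAL_STANDARD_NAMES = tuple(
    f"IS{i + 1:02d}_13C-labeled" for i in range(11)
)

DEFAULT_GROUP_SIZES = {
    "SLE_G1": 10, "SLE_G2": 10, "SLE_G3": 10,
    "pSS": 20, "SSc_lc": 9, "SSc_dc": 10, "HV": 18,
}


class GeneratorError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass
class EffectSpec:
    """Per-feature log-scale group offsets relative to the HV baseline.

    ``offsets[feature][pooled_group]`` is the natural-log fold-change of
    that feature in that cohort versus healthy volunteers.  Healthy
    volunteers are the baseline, so their offset is identically zero and is
    not stored.
    """

    offsets: dict = field(default_factory=dict)

    def delta(self, feature: str, pooled_group: str) -> float:
        if pooled_group == "HV":
            return 0.0
        return float(self.offsets.get(feature, {}).get(pooled_group, 0.0))

    def features(self) -> list[str]:
        return sorted(self.offsets)

    def to_dict(self) -> dict:
        return {f: dict(g) for f, g in self.offsets.items()}


@dataclass
class GeneratorConfig:
    """Cohort-simulation parameters.

    ``injection_sigma`` is the SD of the log injection-efficiency factor
    (the dominant between-sample intensity variation in GC-MS serum data);
    ``noise_sigma`` the SD of per-cell log measurement noise.
    ``block_correlation`` optionally correlates noise within a chemical
    class via a shared per-sample component.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_features: int = 243
    n_identified: int = 73
    n_internal_standards: int = 11
    baseline_log_mean_range: tuple = (2.0, 6.0)
    injection_sigma: float = 0.25
    noise_sigma: float = 0.15
    block_correlation: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_identified > self.n_features:
            raise GeneratorError("n_identified cannot exceed n_features")
        if self.n_identified > len(IDENTIFIED_METABOLITES):
            raise GeneratorError(
                f"at most {len(IDENTIFIED_METABOLITES)} identified names available"
            )
        if self.injection_sigma < 0 or self.noise_sigma < 0:
            raise GeneratorError("sigmas must be nonnegative")
        if self.block_correlation is not None and not (
            0.0 <= self.block_correlation < 1.0
        ):
            raise GeneratorError("block_correlation must be in [0, 1)")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise GeneratorError(f"group {g!r} has size {n}; sizes must be >= 1")


def default_effectspec() -> EffectSpec:
    """The planted disease signatures used throughout testing.

    Versus healthy volunteers: SLE has exactly 5 up- and 15 down-shifted
    identified metabolites (|delta| in [0.4, 1.0]) with tryptophan the
    single largest down-shift; SSc shows fewer depressed amino acids than
    SLE with arginine raised; pSS shows several organic acids raised,
    including fumaric acid, which is lowered in SLE.
    """
    sle_up = {
        "urea": 0.70,
        "uric acid": 0.60,
        "cystine": 0.50,
        "palmitic acid": 0.50,
        "stearic acid": 0.45,
    }
    sle_down = {
        "tryptophan": -1.00,
        "tyrosine": -0.60,
        "arginine": -0.60,
        "ornithine": -0.55,
        "hypoxanthine": -0.60,
        "cysteine": -0.50,
        "fumaric acid": -0.50,
        "2-oxoglutaric acid": -0.50,
        "glutamic acid": -0.45,
        "methionine": -0.45,
        "alanine": -0.45,
        "glycine": -0.40,
        "serine": -0.40,
        "threonine": -0.40,
        "valine": -0.40,
    }
    ssc = {
        "arginine": 0.50,
        "2-oxoglutaric acid": -0.50,
        "alanine": -0.40,
        "glycine": -0.40,
        "serine": -0.40,
        "valine": -0.40,
        "threonine": -0.40,
        "palmitic acid": 0.40,
    }
    pss = {
        "fumaric acid": 0.50,
        "citric acid": 0.45,
        "malic acid": 0.45,
        "succinic acid": 0.40,
        "lactic acid": 0.40,
    }
    offsets: dict = {}
    for name, d in {**sle_up, **sle_down}.items():
        offsets.setdefault(name, {})["SLE"] = d
    for name, d in ssc.items():
        offsets.setdefault(name, {})["SSc"] = d
    for name, d in pss.items():
        offsets.setdefault(name, {})["pSS"] = d
    return EffectSpec(offsets=offsets)


def feature_annotations(config: GeneratorConfig) -> list[FeatureAnnotation]:
    """The generated feature panel: identified, unknown, then IS columns."""
    feats: list[FeatureAnnotation] = []
    rng = np.random.default_rng(config.seed + 101)
    ris = np.sort(rng.uniform(1000.0, 3300.0, size=config.n_features))
    for i in range(config.n_identified):
        name = IDENTIFIED_METABOLITES[i]
        feats.append(
            FeatureAnnotation(
                name=name,
                identified=True,
                chem_class=_CLASS_OF[name],
                retention_index=float(ris[i]),
            )
        )
    for i in range(config.n_features - config.n_identified):
        feats.append(
            FeatureAnnotation(
                name=f"unknown_{i + 1:03d}",
                identified=False,
                chem_class="unknown",
                retention_index=float(ris[config.n_identified + i]),
            )
        )
    for i in range(config.n_internal_standards):
        feats.append(
            FeatureAnnotation(
                name=INTERNAL_STANDARD_NAMES[i]
                if i < len(INTERNAL_STANDARD_NAMES)
                else f"IS{i + 1:02d}_13C-labeled",
                identified=False,
                chem_class="other",
                is_internal_standard=True,
            )
        )
    return feats


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
    effects: Optional[EffectSpec] = None,
    return_truth: bool = False,
) -> tuple:
    """Simulate a full cohort table plus sample metadata.

    With default settings this yields 87 samples × 254 columns (243 putative
    features + 11 internal standards).  A fixed seed gives bitwise-identical
    output.  With ``return_truth`` a third element carries the simulation
    ground truth (per-sample log injection factors, per-feature log
    baselines and the planted effects) for recovery testing.
    """
    if effects is None:
        effects = default_effectspec()
    feats = feature_annotations(config)
    feat_names = [f.name for f in feats]
    unknown_effect = set(effects.offsets) - set(feat_names)
    if unknown_effect:
        raise GeneratorError(
            f"effect features not generated: {sorted(unknown_effect)}"
        )
    pool = {"SLE_G1": "SLE", "SLE_G2": "SLE", "SLE_G3": "SLE",
            "SSc_lc": "SSc", "SSc_dc": "SSc", "pSS": "pSS", "HV": "HV"}
    for g in config.group_sizes:
        if g not in pool:
            raise GeneratorError(f"unknown group {g!r} in group_sizes")

    rng = np.random.default_rng(config.seed)
    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    for g in DEFAULT_GROUP_SIZES:  # canonical group order
        if g not in config.group_sizes:
            continue
        for i in range(config.group_sizes[g]):
            sid = f"{g}_{i + 1:02d}"
            sample_ids.append(sid)
            metadata.append(SampleMetadata(sample_id=sid, group=g))
    n = len(sample_ids)
    k = len(feats)

    lo, hi = config.baseline_log_mean_range
    log_b = rng.uniform(lo, hi, size=k)
    log_f = rng.normal(0.0, config.injection_sigma, size=n)
    delta = np.zeros((n, k))
    for i, m in enumerate(metadata):
        pg = pool[m.group]
        for j, f in enumerate(feats):
            if not f.is_internal_standard:
                delta[i, j] = effects.delta(f.name, pg)

    eps = rng.normal(0.0, config.noise_sigma, size=(n, k))
    if config.block_correlation:
        rho = config.block_correlation
        classes = np.array([f.chem_class for f in feats])
        shared = {c: rng.normal(0.0, config.noise_sigma, size=n)
                  for c in np.unique(classes)}
        for j in range(k):
            eps[:, j] = (
                np.sqrt(rho) * shared[classes[j]] + np.sqrt(1 - rho) * eps[:, j]
            )

    values = np.exp(log_f[:, None] + log_b[None, :] + delta + eps)
    table = MetaboliteTable(values, sample_ids, feats)
    if return_truth:
        truth = {
            "log_injection_factor": log_f,
            "log_baseline": log_b,
            "effects": effects.to_dict(),
        }
        return table, metadata, truth
    return table, metadata


def generate_spectral_fixtures(
    n_compounds: int,
    seed: int = 0,
    intensity_jitter: float = 0.05,
    ri_offset_sd: float = 2.0,
) -> tuple[list[SpectralLibraryEntry], list[tuple], AlkaneSeries]:
    """Synthetic spectral library, query spectra and an alkane ladder.

    Each query is a library spectrum with multiplicative log-normal
    intensity jitter and a Gaussian retention-index offset; the true name is
    returned for recovery testing.  With zero jitter every query self-
    matches at exactly 999.  The ladder spans C10–C40 with strictly
    increasing retention times.
    """
    if n_compounds < 1:
        raise GeneratorError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)

    carbons = list(range(10, 41))
    increments = rng.uniform(20.0, 60.0, size=len(carbons))
    rts = 120.0 + np.cumsum(increments)
    ladder = AlkaneSeries(carbons, rts)

    library: list[SpectralLibraryEntry] = []
    ris = np.sort(rng.uniform(1050.0, 3950.0, size=n_compounds))
    # keep neighboring reference RIs well separated so the window is decisive
    ris = ris + np.arange(n_compounds) * 25.0
    for i in range(n_compounds):
        n_peaks = int(rng.integers(6, 16))
        mzs = rng.choice(np.arange(50, 500), size=n_peaks, replace=False)
        intens = rng.exponential(scale=200.0, size=n_peaks) + 1.0
        spec = MassSpectrum(sorted(zip(mzs.astype(float), intens)))
        library.append(
            SpectralLibraryEntry(
                name=f"compound_{i + 1:03d}", spectrum=spec, reference_ri=float(ris[i])
            )
        )

    queries: list[tuple] = []
    for entry in library:
        if intensity_jitter > 0:
            jit = rng.normal(0.0, intensity_jitter, size=len(entry.spectrum.peaks))
            peaks = [
                (mz, inten * float(np.exp(e)))
                for (mz, inten), e in zip(entry.spectrum.peaks, jit)
            ]
        else:
            peaks = list(entry.spectrum.peaks)
        offset = float(rng.normal(0.0, ri_offset_sd)) if ri_offset_sd > 0 else 0.0
        queries.append(
            (MassSpectrum(peaks), entry.name, entry.reference_ri + offset)
        )
    return library, queries, ladder
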