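"""Synthetic-data generators with known ground truth.

Every downstream stage (MAG screening, bile-acid quantification, network and
mediation analysis) is exercised on data from this module, because the real
inputs live in external sequence-read and metabolomics archives.  The
generators emulate the study conditions: MAG catalogs with planted BAKO
prevalences and CheckM-like quality-score distributions, bile-acid
concentration matrices where exogenous spikes are partially converted along
biotransformation edges (mass-conserving before noise), and
treatment -> mediator -> outcome triads with a planted indirect effect.

All outputs are deterministic functions of the configuration (including its
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baquant import DEFAULT_SCHEME, EXOGENOUS_BAS

__all__ = [
    "SynthConfig",
    "RUMEN_TAXA",
    "gen_mag_catalog",
    "gen_ba_matrix",
    "gen_mediation_data",
    "expected_treated_means",
    "expected_transformed_fraction",
]


def _default_prevalence() -> dict[str, float]:
    # Bernoulli carriage probabilities per screened KO, dominant baiN/BASS/BSH.
    return {
        "K07007": 0.84, "K03453": 0.41, "K01442": 0.12, "K14347": 0.005,
        "K00038": 0.0015, "K00076": 0.0011, "K15868": 0.0008,
        "K01796": 0.0008,
    }


def _default_quality_law() -> dict[str, float]:
    # Completeness ~ Normal(88, 6) clipped to [50, 100];
    # contamination ~ Exponential(mean 3) clipped to [0, 25].
    return {"completeness_mean": 88.0, "completeness_sd": 6.0,
            "contamination_mean": 3.0}


def _default_group_effects() -> dict[str, float]:
    # Multiplicative treated-vs-control effects on baseline concentrations
    # of microbially produced bile acids.
    return {"UDCA": 5.0, "LCA": 4.0, "6-ketoLCA": 6.0, "isoLCA": 3.0,
            "DHLCA": 3.0}


def _default_spikes() -> dict[str, float]:
    # The six supplemented bile acids, nmol/L added to the treated group.
    return {ba: 1000.0 for ba in sorted(EXOGENOUS_BAS)}


def _default_conversions() -> dict[tuple[str, str], float]:
    # Fraction of each spiked substrate converted along one pathway edge.
    return {
        ("CA", "UCA"): 0.15, ("CA", "3-DHCA"): 0.14, ("CA", "alloCA"): 0.13,
        ("HCA", "ω-MCA"): 0.25, ("HCA", "HDCA"): 0.25,
        ("CDCA", "LCA"): 0.27, ("CDCA", "UDCA"): 0.27,
        ("HDCA", "isoHDCA"): 0.15, ("HDCA", "6-ketoLCA"): 0.12,
        ("HDCA", "MDCA"): 0.08,
    }


@dataclass(frozen=True)
class SynthConfig:
    """All knobs for the synthetic generators, with study-like defaults."""

    seed: int = 0
    # MAG catalog
    n_mags: int = 5000
    bako_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    quality_law: dict[str, float] = field(default_factory=_default_quality_law)
    copy_number_mean: float = 1.3     # geometric copy-number law, mean >= 1
    # BA concentration matrix
    n_samples_per_group: int = 6
    baseline_mean: float = 20.0       # nmol/L, log-normal median per BA
    noise_cv: float = 0.2             # multiplicative log-normal CV
    group_effects: dict[str, float] = field(default_factory=_default_group_effects)
    exogenous_spike: dict[str, float] = field(default_factory=_default_spikes)
    conversion_fractions: dict[tuple[str, str], float] = field(
        default_factory=_default_conversions)
    # Mediation triads: a, b, c' and error SDs, sample size
    mediation_params: dict[str, float] = field(default_factory=lambda: {
        "a": 0.8, "b": 0.5, "c_prime": 0.4, "sd_m": 1.0, "sd_y": 1.0,
        "n": 200})

    def __post_init__(self) -> None:
        for ko, p in self.bako_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence for {ko} must be in [0, 1], "
                                 f"got {p}")
        for edge, f in self.conversion_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"conversion fraction for {edge} outside "
                                 "[0, 1]")
        outflow: dict[str, float] = {}
        for (sub, _), f in self.conversion_fractions.items():
            outflow[sub] = outflow.get(sub, 0.0) + f
        bad = {s: f for s, f in outflow.items() if f > 1.0 + 1e-12}
        if bad:
            raise ValueError(f"conversion fractions leaving a node exceed 1: {bad}")
        if self.n_mags <= 0 or self.n_samples_per_group <= 0:
            raise ValueError("counts must be positive")
        if self.copy_number_mean < 1.0:
            raise ValueError("copy_number_mean must be >= 1")
        if int(self.mediation_params.get("n", 0)) < 4:
            raise ValueError("mediation n must be >= 4")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


#: Weighted rumen taxonomy dictionary (GTDB-style strings).  Weights make
#: Lachnospiraceae / Bacteroidaceae / Prevotella dominant; some entries lack
#: a species label so species-level logic is exercised.
_B = "d__Bacteria"
_A = "d__Archaea"
RUMEN_TAXA: list[tuple[str, float]] = [
    (f"{_B};p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Prevotella;s__Prevotella ruminicola", 6.0),
    (f"{_B};p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Prevotella;s__Prevotella copri", 4.0),
    (f"{_B};p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Prevotella;s__Prevotella sp900314947", 3.0),
    (f"{_B};p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Prevotella;s__", 4.0),
    (f"{_B};p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__Bacteroides fragilis", 2.0),
    (f"{_B};p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Muribaculaceae;g__;s__", 1.5),
    (f"{_B};p__Bacteroidota;c__Bacteroidia;o__Bacteroidales;f__Rikenellaceae;g__Alistipes;s__Alistipes sp. CAG_435", 1.5),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Lachnospirales;f__Lachnospiraceae;g__Butyrivibrio;s__Butyrivibrio hungatei", 4.0),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Lachnospirales;f__Lachnospiraceae;g__Butyrivibrio;s__Butyrivibrio fibrisolvens", 3.0),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Lachnospirales;f__Lachnospiraceae;g__Blautia;s__Blautia sp. AM47-4", 2.5),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Lachnospirales;f__Lachnospiraceae;g__Dorea;s__", 2.5),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Lachnospirales;f__Lachnospiraceae;g__Acetatifactor;s__", 2.0),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Oscillospirales;f__Ruminococcaceae;g__Ruminococcus;s__Ruminococcus flavefaciens", 2.5),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Oscillospirales;f__Ruminococcaceae;g__Faecalibacterium;s__", 1.5),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Oscillospirales;f__Acutalibacteraceae;g__UBA1033;s__", 2.5),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Oscillospirales;f__Acutalibacteraceae;g__Acutalibacter;s__Acutalibacter muris", 1.5),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Peptostreptococcales;f__Anaerovoracaceae;g__Anaerosphaera;s__Anaerosphaera sp. GS7.6.2", 1.0),
    (f"{_B};p__Firmicutes_A;c__Clostridia;o__Christensenellales;f__Christensenellaceae;g__;s__", 1.0),
    (f"{_B};p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Lactobacillus;s__Lactobacillus paralimentarius", 1.0),
    (f"{_B};p__Firmicutes;c__Bacilli;o__Bacillales;f__Bacillaceae;g__Bacillus;s__Bacillus licheniformis", 1.0),
    (f"{_B};p__Firmicutes_C;c__Negativicutes;o__Selenomonadales;f__Selenomonadaceae;g__Selenomonas;s__Selenomonas ruminantium", 1.5),
    (f"{_B};p__Firmicutes_C;c__Negativicutes;o__Sporomusales;f__Sporomusaceae;g__Sporomusa;s__Sporomusa ovata", 1.0),
    (f"{_B};p__Firmicutes_C;c__Negativicutes;o__Acidaminococcales;f__Acidaminococcaceae;g__Succiniclasticum;s__Succiniclasticum sp002342505", 1.0),
    (f"{_B};p__Fibrobacterota;c__Fibrobacteria;o__Fibrobacterales;f__Fibrobacteraceae;g__Fibrobacter;s__Fibrobacter succinogenes", 1.5),
    (f"{_B};p__Spirochaetota;c__Spirochaetia;o__Treponematales;f__Treponemataceae;g__Treponema;s__", 1.0),
    (f"{_B};p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;f__Succinivibrionaceae;g__Succinivibrio;s__Succinivibrio dextrinosolvens", 1.0),
    (f"{_B};p__Synergistota;c__Synergistia;o__Synergistales;f__Synergistaceae;g__Fretibacterium;s__Fretibacterium fastidiosum", 0.8),
    (f"{_B};p__Actinobacteriota;c__Coriobacteriia;o__Coriobacteriales;f__Atopobiaceae;g__Olsenella;s__Olsenella umbonata", 0.8),
    (f"{_B};p__Actinobacteriota;c__Actinomycetia;o__Actinomycetales;f__Bifidobacteriaceae;g__Bifidobacterium;s__Bifidobacterium merycicum", 0.8),
    (f"{_B};p__Verrucomicrobiota;c__Kiritimatiellae;o__RFP12;f__UBA1067;g__;s__", 0.8),
    (f"{_A};p__Methanobacteriota;c__Methanobacteria;o__Methanobacteriales;f__Methanobacteriaceae;g__Methanobrevibacter;s__Methanobrevibacter ruminantium", 1.2),
    (f"{_A};p__Halobacteriota;c__Methanosarcinia;o__Methanosarcinales;f__Methanosarcinaceae;g__Methanosarcina;s__Methanosarcina siciliae", 0.5),
]


def gen_mag_catalog(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic MAG catalog plus per-gene KO annotation table.

    Returns ``(mag_table, ko_table)``:  ``mag_table`` has columns mag_id,
    completeness, contamination, taxonomy; ``ko_table`` has one row per gene
    (gene_id, mag_id, ko_id).  Carriage of each BAKO is an independent
    Bernoulli draw at its planted prevalence; carriers get a geometric copy
    number (mean ``copy_number_mean``).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_mags
    q = cfg.quality_law
    completeness = np.clip(
        rng.normal(q["completeness_mean"], q["completeness_sd"], n), 50.0, 100.0)
    contamination = np.clip(
        rng.exponential(q["contamination_mean"], n), 0.0, 25.0)
    weights = np.array([w for _, w in RUMEN_TAXA])
    taxa_idx = rng.choice(len(RUMEN_TAXA), size=n, p=weights / weights.sum())

    mag_ids = [f"MAG{i:05d}" for i in range(n)]
    mag_table = pd.DataFrame({
        "mag_id": mag_ids,
        "completeness": np.round(completeness, 2),
        "contamination": np.round(contamination, 2),
        "taxonomy": [RUMEN_TAXA[i][0] for i in taxa_idx],
    })

    p_geom = 1.0 / cfg.copy_number_mean
    gene_rows = []
    gene_serial = 0
    kos = sorted(cfg.bako_prevalence)
    carriage = {ko: rng.random(n) < cfg.bako_prevalence[ko] for ko in kos}
    copies = {ko: rng.geometric(p_geom, n) for ko in kos}
    for i, mag_id in enumerate(mag_ids):
        for ko in kos:
            if carriage[ko][i]:
                for _ in range(int(copies[ko][i])):
                    gene_rows.append((f"gene{gene_serial:07d}", mag_id, ko))
                    gene_serial += 1
    ko_table = pd.DataFrame(gene_rows, columns=["gene_id", "mag_id", "ko_id"])
    return mag_table, ko_table


def _ba_universe(cfg: SynthConfig) -> list[str]:
    names = sorted(DEFAULT_SCHEME.primary | DEFAULT_SCHEME.secondary |
                   DEFAULT_SCHEME.unclassified | set(cfg.exogenous_spike) |
                   set(cfg.group_effects))
    for sub, prod in cfg.conversion_fractions:
        for name in (sub, prod):
            if name not in names:
                raise ValueError(f"conversion edge references unknown BA "
                                 f"{name!r}")
    return names


def expected_treated_means(cfg: SynthConfig) -> pd.Series:
    """Noise-free expected treated-group concentrations per bile acid.

    Treated mean = baseline x group effect + net spike allocation after one
    round of conversion along the configured edges (mass conserving).
    """
    names = _ba_universe(cfg)
    base = pd.Series(cfg.baseline_mean, index=names, dtype=float)
    for ba, eff in cfg.group_effects.items():
        base[ba] *= eff
    spike = pd.Series(0.0, index=names)
    for ba, amount in cfg.exogenous_spike.items():
        spike[ba] += amount
    moved = pd.Series(0.0, index=names)
    for (sub, prod), frac in cfg.conversion_fractions.items():
        amount = cfg.exogenous_spike.get(sub, 0.0) * frac
        moved[sub] -= amount
        moved[prod] += amount
    return base + spike + moved


def expected_transformed_fraction(cfg: SynthConfig) -> float:
    """Analytic transformed fraction of the treated pool (no noise)."""
    means = expected_treated_means(cfg)
    exo = {b for b in EXOGENOUS_BAS}
    non_exo = sum(v for ba, v in means.items() if ba not in exo)
    return float(non_exo / means.sum())


def gen_ba_matrix(cfg: SynthConfig):
    """Synthetic control/treated bile-acid concentration matrix.

    Control samples draw each BA around the log-normal baseline; treated
    samples draw around the expected treated means (baseline x effect plus
    converted spikes).  Multiplicative log-normal noise at CV ``noise_cv``.
    Returns a :class:`~rumenba.baquant.ConcentrationMatrix`.
    """
    from .baquant import ConcentrationMatrix

    rng = np.random.default_rng(cfg.seed + 1)
    names = _ba_universe(cfg)
    n = cfg.n_samples_per_group
    control_means = pd.Series(cfg.baseline_mean, index=names, dtype=float)
    treated_means = expected_treated_means(cfg)

    cv = cfg.noise_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        mu_shift = -sigma**2 / 2.0     # keep the arithmetic mean at target
        def noisy(means, size):
            ln = rng.lognormal(mu_shift, sigma, size=(size, len(names)))
            return means.to_numpy() * ln
    else:
        def noisy(means, size):
            return np.tile(means.to_numpy(), (size, 1))

    values = np.vstack([noisy(control_means, n), noisy(treated_means, n)])
    sample_ids = [f"C{i+1:02d}" for i in range(n)] + \
                 [f"T{i+1:02d}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["treated"] * n, index=sample_ids,
                       name="group")
    df = pd.DataFrame(values, index=sample_ids, columns=names)
    return ConcentrationMatrix(values=df, groups=groups)


def gen_mediation_data(cfg: SynthConfig, n: int | None = None):
    """Treatment/mediator/outcome triad with a planted indirect effect.

    T is balanced binary; M = a*T + e_M; Y = c'*T + b*M + e_Y with independent
    Gaussian errors.  Returns a dict with the three vectors and the ground
    truth (ACME = a*b, ADE = c', total, proportion mediated).
    """
    p = cfg.mediation_params
    n = int(p["n"]) if n is None else int(n)
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(cfg.seed + 2)
    t = np.zeros(n)
    t[: n // 2] = 1.0
    rng.shuffle(t)
    if t.std() == 0:   # n < 2 safeguard; unreachable for n >= 4
        t[0] = 1.0
    m = p["a"] * t + rng.normal(0.0, p["sd_m"], n)
    y = p["c_prime"] * t + p["b"] * m + rng.normal(0.0, p["sd_y"], n)
    acme = p["a"] * p["b"]
    total = acme + p["c_prime"]
    return {
        "treatment": t, "mediator": m, "outcome": y,
        "truth": {
            "a": p["a"], "b": p["b"], "c_prime": p["c_prime"],
            "acme": acme, "total": total,
            "prop_mediated": acme / total if total != 0 else np.nan,
        },
    }
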