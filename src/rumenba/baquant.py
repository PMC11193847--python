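"""Quantitative bile-acid pool accounting and group comparison.

Concentrations are nmol/L after dilution correction (C_M = C_F * V_F / V_S).
Bile acids are classified as primary (liver-derived), secondary (microbially
transformed) or unclassified following the targeted-metabolomics scheme used
for rumen and serum panels; a measured name absent from the scheme is flagged
``unknown`` rather than dropped.  Differential bile acids are those passing
the joint rule VIP > 1 (single-component PLS-DA) and two-sample test p < alpha.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

log = logging.getLogger(__name__)

__all__ = [
    "BAClassScheme",
    "ConcentrationMatrix",
    "DEFAULT_SCHEME",
    "EXOGENOUS_BAS",
    "MUTUAL_DIFFERENTIAL_BAS",
    "dilute_concentration",
    "normalize_ba_name",
    "classify_bas",
    "pool_totals",
    "transformed_fraction",
    "differential_bas",
    "mutual_differentials",
]


def dilute_concentration(c_f, v_f, v_s):
    """Dilution-corrected concentration: C_M = C_F * V_F / V_S (nmol/L).

    ``c_f`` is the measured concentration (nmol/L), ``v_f`` the final diluted
    volume (uL) and ``v_s`` the sample volume (uL).  Accepts scalars or arrays.
    """
    c_f = np.asarray(c_f, dtype=float)
    v_f = np.asarray(v_f, dtype=float)
    v_s = np.asarray(v_s, dtype=float)
    if np.any(v_s == 0):
        raise ValueError("sample volume V_S must be positive")
    if np.any(c_f < 0) or np.any(v_f < 0) or np.any(v_s < 0):
        raise ValueError("concentrations and volumes must be non-negative")
    out = c_f * v_f / v_s
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Name normalisation


def _canon_key(name: str) -> str:
    """Casefolded comparison key; Greek letters and digits preserved."""
    s = unicodedata.normalize("NFC", name).strip()
    s = re.sub(r"\s+", " ", s)
    return s.casefold()


#: Synonym table: full printed name (or spelling variant) -> canonical id.
_SYNONYMS: dict[str, str] = {_canon_key(k): v for k, v in {
    "cholic acid": "CA",
    "chenodeoxycholic acid": "CDCA",
    "deoxycholic acid": "DCA",
    "lithocholic acid": "LCA",
    "hyocholic acid": "HCA",
    "hyodeoxycholic acid": "HDCA",
    "ursodeoxycholic acid": "UDCA",
    "ursocholic acid": "UCA",
    "allocholic acid": "alloCA",
    "isolithocholic acid": "isoLCA",
    "isoursodeoxycholic acid": "isoUDCA",
    "isohyodeoxycholic acid": "isoHDCA",
    "murideoxycholic acid": "MDCA",
    "dehydrolithocholic acid": "DHLCA",
    "dehydrocholic acid": "DHCA",
    "ω-muricholic acid": "ω-MCA",
    "omega-muricholic acid": "ω-MCA",
    "omega-mca": "ω-MCA",
    "α-muricholic acid": "α-MCA",
    "alpha-muricholic acid": "α-MCA",
    "alpha-mca": "α-MCA",
    "β-muricholic acid": "β-MCA",
    "beta-muricholic acid": "β-MCA",
    "beta-mca": "β-MCA",
    "3-epideoxycholic acid": "3-epiDCA",
    "3beta-cholic acid": "3β-CA",
    "3beta-ca": "3β-CA",
    "taurocholic acid": "TCA",
    "taurochenodeoxycholic acid": "TCDCA",
    "glycocholic acid": "GCA",
    "glycohyocholic acid": "GlyHCA",
    "glycolithocholic acid-3-sulfate": "GlyLCA-3-sulfate",
    "glycodehydrocholic acid": "GlyDHCA",
    "6-ketolda": "6-ketoLCA",   # printed-variant spelling
}.items()}

#: Canonical ids, keyed by their own comparison key (for case folding).
_CANONICAL: dict[str, str] = {}
for _id in ["CA", "CDCA", "DCA", "LCA", "HCA", "HDCA", "UDCA", "UCA",
            "alloCA", "isoLCA", "isoUDCA", "isoHDCA", "MDCA", "DHLCA",
            "DHCA", "ω-MCA", "α-MCA", "β-MCA", "3-epiDCA", "3β-CA",
            "3-DHCA", "12-DHCA", "6-ketoLCA", "7-ketoLCA", "12-ketoLCA",
            "7-ketoDCA", "7,12-diketoLCA", "6,7-diketoLCA",
            "CDCA-3-sulfate", "GCA-3-sulfate", "UDCA-3-sulfate",
            "GlyLCA-3-sulfate", "GlyDHCA", "GlyHCA",
            "TCA", "TCDCA", "GCA"]:
    _CANONICAL[_canon_key(_id)] = _id


def normalize_ba_name(raw: str) -> str:
    """Canonical bile-acid identifier for a printed name.

    Handles "full name (ABBR)" forms by extracting the abbreviation, applies
    the shipped synonym table, and falls back to the cleaned input for names
    outside the table (so unknown analytes survive round-trips).
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("empty bile-acid name")
    s = unicodedata.normalize("NFC", raw).strip()
    s = re.sub(r"\s+", " ", s)
    m = re.match(r"^(?P<full>[^()]+?)\s*\((?P<abbr>[^()]+)\)$", s)
    if m:
        for candidate in (m.group("abbr"), m.group("full")):
            key = _canon_key(candidate)
            if key in _CANONICAL:
                return _CANONICAL[key]
            if key in _SYNONYMS:
                return _SYNONYMS[key]
        s = m.group("abbr").strip()
    key = _canon_key(s)
    if key in _CANONICAL:
        return _CANONICAL[key]
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    return s


# ---------------------------------------------------------------------------
# Classification scheme


@dataclass(frozen=True)
class BAClassScheme:
    """Disjoint primary / secondary / unclassified bile-acid name sets."""

    primary: frozenset[str]
    secondary: frozenset[str]
    unclassified: frozenset[str]

    def __post_init__(self) -> None:
        overlap = (self.primary & self.secondary) | \
                  (self.primary & self.unclassified) | \
                  (self.secondary & self.unclassified)
        if overlap:
            raise ValueError(f"scheme sets overlap: {sorted(overlap)}")

    def lookup(self, canonical_name: str) -> str:
        if canonical_name in self.primary:
            return "primary"
        if canonical_name in self.secondary:
            return "secondary"
        if canonical_name in self.unclassified:
            return "unclassified"
        return "unknown"


DEFAULT_SCHEME = BAClassScheme(
    primary=frozenset({"CDCA", "3β-CA", "ω-MCA", "α-MCA", "β-MCA", "HCA",
                       "CA", "CDCA-3-sulfate", "GCA-3-sulfate"}),
    secondary=frozenset({"isoLCA", "LCA", "7-ketoLCA", "12-ketoLCA", "MDCA",
                         "isoUDCA", "isoHDCA", "UDCA", "HDCA", "3-epiDCA",
                         "DCA", "7,12-diketoLCA", "6,7-diketoLCA",
                         "7-ketoDCA", "alloCA", "UDCA-3-sulfate",
                         "GlyLCA-3-sulfate"}),
    unclassified=frozenset({"DHLCA", "6-ketoLCA", "DHCA", "12-DHCA",
                            "3-DHCA", "UCA", "GlyDHCA"}),
)

#: The six supplemented (exogenous) bile acids in the feeding experiments.
EXOGENOUS_BAS = frozenset({"HCA", "CDCA", "CA", "HDCA", "TCDCA", "TCA"})

#: Bile acids significantly increased in both the in-vitro and in-vivo trials.
MUTUAL_DIFFERENTIAL_BAS = [
    "UDCA", "6-ketoLCA", "HDCA", "HCA", "3-DHCA", "3β-CA", "alloCA", "LCA",
    "UCA", "MDCA", "ω-MCA", "isoHDCA", "isoLCA", "CDCA", "DHLCA",
]


def classify_bas(names, scheme: BAClassScheme = DEFAULT_SCHEME) -> dict[str, str]:
    """Map each (normalised) name to primary/secondary/unclassified/unknown."""
    out: dict[str, str] = {}
    for name in names:
        canon = normalize_ba_name(name)
        out[name] = scheme.lookup(canon)
    return out


# ---------------------------------------------------------------------------
# Concentration matrices


@dataclass
class ConcentrationMatrix:
    """Samples x bile acids concentration table (nmol/L) with group labels."""

    values: pd.DataFrame          # index: sample ids, columns: BA names
    groups: pd.Series             # index: sample ids, values: group label
    provenance: pd.DataFrame | None = None  # optional (C_F, V_F, V_S) records

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValueError("sample ids of values and groups differ")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate bile-acid columns")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("concentrations must be non-negative")
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            log.info("concentration matrix has %d missing cells; treated as "
                     "absent (0 in totals, excluded from tests)", n_missing)

    @property
    def bas(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values.loc[self.groups == group]


def pool_totals(matrix: ConcentrationMatrix,
                scheme: BAClassScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Per-sample primary, secondary and total bile-acid pool sums.

    The total includes unclassified and unknown analytes, so
    primary + secondary <= total always.
    """
    classes = classify_bas(matrix.bas, scheme)
    vals = matrix.values.fillna(0.0)
    primary_cols = [c for c in matrix.bas if classes[c] == "primary"]
    secondary_cols = [c for c in matrix.bas if classes[c] == "secondary"]
    return pd.DataFrame({
        "primary_total": vals[primary_cols].sum(axis=1),
        "secondary_total": vals[secondary_cols].sum(axis=1),
        "total": vals.sum(axis=1),
        "group": matrix.groups,
    })


def transformed_fraction(group_means: pd.Series,
                         exogenous=EXOGENOUS_BAS) -> float:
    """Fraction of the pool held by bile acids outside the exogenous set.

    ``group_means`` is a Series of per-BA mean concentrations for one group.
    The fraction is mass-weighted: sum over non-exogenous / sum over all.
    """
    exogenous = {normalize_ba_name(b) for b in exogenous}
    if not exogenous:
        raise ValueError("exogenous set must be non-empty")
    means = group_means.fillna(0.0)
    total = float(means.sum())
    if total <= 0:
        raise ValueError("total bile-acid concentration is zero")
    non_exo = sum(v for name, v in means.items()
                  if normalize_ba_name(str(name)) not in exogenous)
    return float(non_exo) / total


@dataclass(frozen=True)
class DifferentialConfig:
    test: str = "student_t"       # student_t | wilcoxon
    alpha: float = 0.05
    vip_threshold: float = 1.0
    welch: bool = False
    n_components: int = 1


def differential_bas(matrix: ConcentrationMatrix,
                     groups: tuple[str, str],
                     config: DifferentialConfig = DifferentialConfig(),
                     ) -> pd.DataFrame:
    """Differential bile acids by the joint VIP > threshold AND p < alpha rule.

    Returns one row per bile acid with columns name, class, p, vip, direction
    and significant.  ``direction`` is the sign of treated minus control mean
    (groups = (control, treated)).  A zero-variance analyte gets vip = NaN and
    is flagged non-significant.
    """
    control, treated = groups
    a = matrix.group_values(control)
    b = matrix.group_values(treated)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 samples per group")

    names = matrix.bas
    classes = classify_bas(names)
    X = pd.concat([a, b]).fillna(0.0)
    y = np.array([0] * len(a) + [1] * len(b))

    col_sd = X.std(axis=0, ddof=1).to_numpy()
    live = col_sd > 0
    vip = np.full(len(names), np.nan)
    if live.sum() >= 1:
        fit = stats.plsda_vip(X.loc[:, live].to_numpy(), y,
                              n_components=config.n_components)
        vip[live] = fit.vip

    rows = []
    for j, name in enumerate(names):
        xa = a[name].dropna().to_numpy()
        xb = b[name].dropna().to_numpy()
        degenerate = not live[j]
        if degenerate:
            p = 1.0
        elif config.test == "wilcoxon":
            p = stats.wilcoxon_rank_sum(xa, xb).p_value
        else:
            p = stats.student_t(xa, xb, welch=config.welch).p_value
        direction = float(np.sign(np.mean(xb) - np.mean(xa))) if xa.size and xb.size else 0.0
        significant = (not degenerate and not np.isnan(vip[j])
                       and vip[j] > config.vip_threshold and p < config.alpha)
        rows.append({"name": name, "class": classes[name], "p": p,
                     "vip": vip[j], "direction": direction,
                     "significant": bool(significant),
                     "degenerate": degenerate})
    return pd.DataFrame(rows)


def mutual_differentials(list_a, list_b, effects_a: dict | None = None) -> list[str]:
    """Intersection of two differential lists on canonical names.

    Ordered by descending |effect| from ``effects_a`` when supplied, else
    alphabetically.
    """
    ca = {normalize_ba_name(x) for x in list_a}
    cb = {normalize_ba_name(x) for x in list_b}
    common = ca & cb
    if effects_a:
        eff = {normalize_ba_name(k): abs(v) for k, v in effects_a.items()}
        return sorted(common, key=lambda n: (-eff.get(n, 0.0), n))
    return sorted(common)
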