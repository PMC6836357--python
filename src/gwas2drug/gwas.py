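"""Marker-level QC and additive-model association for case/control genotype tables.

Genotypes are coded as alternate-allele dosages 0/1/2; missing values are NaN.
The QC rules are the standard array-QC trio: minor-allele frequency, per-group
call rate, and an exact Hardy-Weinberg equilibrium test evaluated in controls.
Association under the additive model is the Cochran-Armitage trend test, which
is identical to the score test of a logistic regression of status on dosage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "GenotypeCounts",
    "MarkerQcResult",
    "AssociationResult",
    "QcFailure",
    "compute_maf",
    "hwe_exact_test",
    "additive_association",
    "marker_qc",
    "association_scan",
    "genotype_counts",
]


class QcFailure(str, Enum):
    """Reasons a marker can fail QC."""

    LOW_MAF = "low_maf"
    LOW_CALL_RATE = "low_call_rate"
    HWE_FAIL = "hwe_fail"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one biallelic marker.

    ``n_ref_hom``, ``n_het``, ``n_alt_hom`` count typed samples by alternate
    allele dosage (0, 1, 2); ``n_missing`` counts untyped samples.
    """

    n_ref_hom: int
    n_het: int
    n_alt_hom: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ref_hom", "n_het", "n_alt_hom", "n_missing"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_typed(self) -> int:
        return self.n_ref_hom + self.n_het + self.n_alt_hom

    @property
    def n_total(self) -> int:
        return self.n_typed + self.n_missing

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_alt_hom + self.n_het

    @property
    def call_rate(self) -> float:
        if self.n_total == 0:
            raise ValueError("no samples at all: call rate undefined")
        return self.n_typed / self.n_total

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_ref_hom + other.n_ref_hom,
            self.n_het + other.n_het,
            self.n_alt_hom + other.n_alt_hom,
            self.n_missing + other.n_missing,
        )


@dataclass(frozen=True)
class MarkerQcResult:
    snp_id: str
    maf: float
    call_rate_case: float
    call_rate_control: float
    hwe_p_controls: float
    passed: bool
    fail_reasons: tuple[QcFailure, ...]


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    statistic: float  # signed trend z; chi-square(1) statistic is z**2
    p_value: float


def genotype_counts(genotypes: pd.Series | np.ndarray) -> GenotypeCounts:
    """Count 0/1/2/NaN codes in one marker column."""
    arr = np.asarray(genotypes, dtype=float)
    n_missing = int(np.isnan(arr).sum())
    typed = arr[~np.isnan(arr)]
    if typed.size and not np.isin(typed, (0.0, 1.0, 2.0)).all():
        bad = sorted(set(typed) - {0.0, 1.0, 2.0})
        raise ValueError(f"genotype codes must be 0/1/2/NaN; found {bad}")
    return GenotypeCounts(
        int((typed == 0).sum()), int((typed == 1).sum()), int((typed == 2).sum()), n_missing
    )


def compute_maf(counts: GenotypeCounts) -> float:
    """Minor-allele frequency from genotype counts (always in [0, 0.5])."""
    if counts.n_typed == 0:
        raise ValueError("no typed genotypes: MAF undefined")
    q = counts.n_alt_alleles / (2 * counts.n_typed)
    return min(q, 1.0 - q)


def _hwe_log_probs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote counts compatible with (n genotypes, n_minor minor alleles)
    and their log probabilities under the exact conditional HWE null."""
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    ok = hom_major >= 0
    hets, hom_minor, hom_major = hets[ok], hom_minor[ok], hom_major[ok]
    n_major = 2 * n - n_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one
    (the two-sided "less likely or equal" convention of Wigginton et al.).
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError("no typed genotypes: HWE test undefined")
    n_minor = min(counts.n_alt_alleles, 2 * n - counts.n_alt_alleles)
    obs_het = counts.n_het
    hets, logp = _hwe_log_probs(n, n_minor)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = float(probs[hets == obs_het][0])
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(1.0, p)


_TREND_WEIGHTS = np.array([0.0, 1.0, 2.0])


def _trend_stat(r: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Cochran-Armitage trend z and p. r, s: (..., 3) genotype
    counts for cases and controls. Zero-variance rows yield NaN."""
    n = r + s
    N = n.sum(axis=-1)
    R = r.sum(axis=-1)
    w = _TREND_WEIGHTS
    with np.errstate(invalid="ignore", divide="ignore"):
        U = r @ w - (R / N) * (n @ w)
        V = (R / N) * (1.0 - R / N) * (n @ w**2 - (n @ w) ** 2 / N)
        z = np.where(V > 0, U / np.sqrt(np.where(V > 0, V, 1.0)), np.nan)
        p = chi2.sf(z**2, df=1)
    return z, p


def additive_association(
    case_counts: GenotypeCounts, control_counts: GenotypeCounts, snp_id: str = ""
) -> AssociationResult:
    """Cochran-Armitage trend test with additive weights (0, 1, 2).

    The squared standardized trend statistic is referred to the chi-square(1)
    upper tail; it coincides with the logistic-regression score test.
    """
    if case_counts.n_typed == 0 or control_counts.n_typed == 0:
        raise ValueError("both groups need typed genotypes")
    r = np.array([case_counts.n_ref_hom, case_counts.n_het, case_counts.n_alt_hom], float)
    s = np.array(
        [control_counts.n_ref_hom, control_counts.n_het, control_counts.n_alt_hom], float
    )
    z, p = _trend_stat(r, s)
    if np.isnan(z):
        raise ValueError("trend statistic undefined: marker monomorphic in pooled samples")
    return AssociationResult(snp_id=snp_id, statistic=float(z), p_value=float(p))


def _count_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP genotype class counts for a samples x SNPs dosage table."""
    vals = df.to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "n_ref_hom": (vals == 0).sum(axis=0),
            "n_het": (vals == 1).sum(axis=0),
            "n_alt_hom": (vals == 2).sum(axis=0),
            "n_missing": np.isnan(vals).sum(axis=0),
        },
        index=df.columns,
    )
    typed = out[["n_ref_hom", "n_het", "n_alt_hom"]].sum(axis=1)
    if not (typed + out["n_missing"] == len(df)).all():
        raise ValueError("genotype codes must be 0/1/2/NaN")
    return out


def _check_same_snps(cases: pd.DataFrame, controls: pd.DataFrame) -> None:
    missing = set(cases.columns).symmetric_difference(controls.columns)
    if missing:
        raise KeyError(f"SNPs not present in both groups: {sorted(missing)[:10]}")


def marker_qc(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.98,
    hwe_alpha: float = 1e-4,
    maf_group: str = "pooled",
) -> pd.DataFrame:
    """Apply the three marker-level QC rules to every SNP.

    A SNP fails if MAF < ``maf_min`` (pooled typed samples by default,
    ``maf_group='controls'`` for controls only), if call rate < ``call_rate_min``
    in *either* group, or if the exact HWE p in controls < ``hwe_alpha``.
    Returns one row per SNP with all triggered reasons enumerated.
    """
    if maf_group not in ("pooled", "controls"):
        raise ValueError("maf_group must be 'pooled' or 'controls'")
    _check_same_snps(cases, controls)
    controls = controls[cases.columns]
    cc = _count_matrix(cases)
    nc = _count_matrix(controls)
    rows = []
    for snp in cases.columns:
        case_counts = GenotypeCounts(*cc.loc[snp].astype(int))
        ctrl_counts = GenotypeCounts(*nc.loc[snp].astype(int))
        maf_counts = ctrl_counts if maf_group == "controls" else case_counts + ctrl_counts
        maf = compute_maf(maf_counts)
        cr_case = case_counts.call_rate
        cr_ctrl = ctrl_counts.call_rate
        hwe_p = hwe_exact_test(ctrl_counts)
        reasons: list[QcFailure] = []
        if maf < maf_min:
            reasons.append(QcFailure.LOW_MAF)
        if cr_case < call_rate_min or cr_ctrl < call_rate_min:
            reasons.append(QcFailure.LOW_CALL_RATE)
        if hwe_p < hwe_alpha:
            reasons.append(QcFailure.HWE_FAIL)
        rows.append(
            {
                "snp_id": snp,
                "maf": maf,
                "call_rate_case": cr_case,
                "call_rate_control": cr_ctrl,
                "hwe_p_controls": hwe_p,
                "passed": not reasons,
                "fail_reasons": ",".join(r.value for r in reasons),
            }
        )
    return pd.DataFrame(rows).set_index("snp_id", drop=False)


def association_scan(
    cases: pd.DataFrame, controls: pd.DataFrame, snps: list[str] | None = None
) -> pd.DataFrame:
    """Trend-test every SNP; returns a table sorted by p.

    Markers monomorphic in the pooled sample have an undefined statistic and
    are reported with NaN statistic and p = 1 rather than erroring the scan.
    """
    _check_same_snps(cases, controls)
    cols = list(snps) if snps is not None else list(cases.columns)
    r = _count_matrix(cases[cols])[["n_ref_hom", "n_het", "n_alt_hom"]].to_numpy(float)
    s = _count_matrix(controls[cols])[["n_ref_hom", "n_het", "n_alt_hom"]].to_numpy(float)
    z, p = _trend_stat(r, s)
    out = pd.DataFrame(
        {"snp_id": cols, "statistic": z, "p_value": np.where(np.isnan(z), 1.0, p)}
    )
    return out.sort_values(["p_value", "snp_id"], kind="mergesort").reset_index(drop=True)
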