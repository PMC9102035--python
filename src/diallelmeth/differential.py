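"""Differential-methylation calling between two unreplicated count columns.

The test is the classic exact test for negative-binomial counts without
replicates: the two libraries are equalised by proportional scaling to their
geometric-mean depth, and the observed split of the (scaled) total between the
two samples is compared with its conditional null distribution.  For two NB
observations with equal means and dispersion ``phi`` (variance mu + phi*mu^2,
i.e. size r = 1/phi), the split conditioned on the total is negative
hypergeometric:

    P(a | a + b = n) = C(a + r - 1, a) * C(n - a + r - 1, n - a) / C(n + 2r - 1, n)

which degenerates to Binomial(n, 1/2) at phi = 0.  The two-sided p-value is
the sum of probabilities of all outcomes no more probable than the observed
one (a doubled-one-tail variant is available).  A site is called a DMS when
|log2FC| > 1 and p < 0.05, the study thresholds.

Without replicates the dispersion cannot be estimated from the data; it is a
fixed, explicit parameter (default phi = 0.01, i.e. a biological coefficient
of variation of 0.1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import SiteCountTable, Thresholds

DEFAULT_DISPERSION = 0.01
_TIE_REL_TOL = 1e-8  # relative slack when collecting outcomes tied with the observed


def _conditional_log_pmf(total: int, dispersion: float) -> np.ndarray:
    """log P(a | a+b=total) for a = 0..total under equalised libraries."""
    a = np.arange(total + 1)
    log_binom = gammaln(total + 1) - gammaln(a + 1) - gammaln(total - a + 1)
    r = np.inf if dispersion == 0.0 else 1.0 / dispersion
    if not np.isfinite(r) or r > 1e15:
        # Binomial(total, 1/2) limit; the NB correction is O(total^2/r)
        return log_binom - total * np.log(2.0)
    # gammaln(a+r) - gammaln(r) as a running sum of log(r+i): stable for any
    # r, unlike direct gammaln differences which cancel at large r
    i = np.arange(total, dtype=np.float64)
    rising_r = np.concatenate([[0.0], np.cumsum(np.log(r + i))])
    rising_2r = float(np.log(2 * r + i).sum())
    return log_binom + rising_r[a] + rising_r[total - a] - rising_2r


def _pvalues_for_total(a_obs: np.ndarray, total: int, dispersion: float,
                       two_sided: str) -> np.ndarray:
    """Exact p-values for all observations sharing one conditional total."""
    logpmf = _conditional_log_pmf(total, dispersion)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    if two_sided == "smallp":
        order = np.argsort(pmf, kind="stable")
        cum = np.cumsum(pmf[order])
        sorted_pmf = pmf[order]
        idx = np.searchsorted(sorted_pmf, pmf[a_obs] * (1.0 + _TIE_REL_TOL), side="right")
        return np.minimum(cum[idx - 1], 1.0)
    if two_sided == "doubletail":
        cdf = np.cumsum(pmf)
        lower = cdf[a_obs]
        upper = 1.0 - cdf[a_obs] + pmf[a_obs]
        return np.minimum(2.0 * np.minimum(lower, upper), 1.0)
    raise ValueError(f"unknown two-sided method {two_sided!r}")


def exact_test_arrays(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: float,
    lib_b: float,
    dispersion: float = DEFAULT_DISPERSION,
    two_sided: str = "smallp",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised exact test over aligned count vectors.

    Returns ``(log2fc, p)`` with log2fc = log2 of sample-b over sample-a
    normalised abundance, with a 0.5 pseudocount on the library-equalised
    counts (so two all-zero columns give log2fc exactly 0).
    """
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    counts_a = np.asarray(counts_a, dtype=np.float64)
    counts_b = np.asarray(counts_b, dtype=np.float64)
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("counts must be non-negative")
    gm = float(np.sqrt(lib_a * lib_b))
    eq_a = counts_a * (gm / lib_a)
    eq_b = counts_b * (gm / lib_b)
    log2fc = np.log2(eq_b + 0.5) - np.log2(eq_a + 0.5)
    a = np.rint(eq_a).astype(np.int64)
    b = np.rint(eq_b).astype(np.int64)
    total = a + b
    p = np.ones(len(a), dtype=np.float64)
    for t in np.unique(total[total > 0]):
        mask = total == t
        p[mask] = _pvalues_for_total(a[mask], int(t), dispersion, two_sided)
    return log2fc, p


def nb_exact_test(
    count_a: int,
    count_b: int,
    lib_a: float,
    lib_b: float,
    dispersion: float = DEFAULT_DISPERSION,
    two_sided: str = "smallp",
) -> tuple[float, float]:
    """Scalar exact test; see :func:`exact_test_arrays`."""
    lfc, p = exact_test_arrays(
        np.array([count_a]), np.array([count_b]), lib_a, lib_b, dispersion, two_sided
    )
    return float(lfc[0]), float(p[0])


def make_mpv(
    rpm_a: np.ndarray, rpm_b: np.ndarray, reference_size: int = 1_000_000
) -> tuple[np.ndarray, int]:
    """Mid-parent value as integer pseudo-counts on a reference library scale.

    MPV is the average of the two parents' RPM values — the additive
    expectation for a hybrid — re-expressed as counts so the exact test
    applies unchanged: ``round(reference_size * (rpm_a + rpm_b) / 2e6)``.
    """
    if reference_size <= 0:
        raise ValueError("reference_size must be positive")
    pseudo = np.rint(reference_size * (np.asarray(rpm_a) + np.asarray(rpm_b)) / 2e6)
    return pseudo.astype(np.int64), reference_size


def call_dms(
    sites: pd.DataFrame,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: float,
    lib_b: float,
    name_a: str,
    name_b: str,
    dispersion: float = DEFAULT_DISPERSION,
    thresholds: Thresholds = Thresholds(),
    two_sided: str = "smallp",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-site DMS records for one comparison (columns: site metadata,
    comparison names, log2fc, p_value, significant).

    ``log2fc`` is log2(B/A); ``significant`` is the conjunction
    |log2fc| > thresholds.log2fc AND p < thresholds.p_value.  With
    ``bh_correct`` the p used for the call is Benjamini–Hochberg adjusted
    (off by default; the study used raw p).
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    if len(counts_a) != len(sites) or len(counts_b) != len(sites):
        mism = abs(len(counts_a) - len(sites)) + abs(len(counts_b) - len(sites))
        raise ValueError(f"site universes differ between inputs ({mism} rows mismatched)")
    log2fc, p = exact_test_arrays(counts_a, counts_b, lib_a, lib_b, dispersion, two_sided)
    p_call = p
    if bh_correct:
        from scipy.stats import false_discovery_control

        p_call = false_discovery_control(p, method="bh")
    out = sites[["chrom", "pos", "context"]].copy()
    out["sample_a"] = name_a
    out["sample_b"] = name_b
    out["log2fc"] = log2fc
    out["p_value"] = p
    out["significant"] = (np.abs(log2fc) > thresholds.log2fc) & (p_call < thresholds.p_value)
    return out


def compare_samples(
    table: SiteCountTable,
    name_a: str,
    name_b: str,
    dispersion: float = DEFAULT_DISPERSION,
    thresholds: Thresholds = Thresholds(),
    **kwargs,
) -> pd.DataFrame:
    """DMS calling between two columns of a count table."""
    return call_dms(
        table.sites,
        table.column(name_a),
        table.column(name_b),
        table.library_size(name_a),
        table.library_size(name_b),
        name_a,
        name_b,
        dispersion,
        thresholds,
        **kwargs,
    )


def compare_to_mpv(
    table: SiteCountTable,
    hybrid: str,
    parent_a: str,
    parent_b: str,
    dispersion: float = DEFAULT_DISPERSION,
    thresholds: Thresholds = Thresholds(),
    reference_size: int = 1_000_000,
    **kwargs,
) -> pd.DataFrame:
    """DMS calling of a hybrid against the mid-parent value of two parents.

    log2fc > 0 means the hybrid is hyper-methylated relative to MPV.
    """
    rpm_a = table.column(parent_a) / table.library_size(parent_a) * 1e6
    rpm_b = table.column(parent_b) / table.library_size(parent_b) * 1e6
    mpv_counts, ref = make_mpv(rpm_a, rpm_b, reference_size)
    return call_dms(
        table.sites,
        mpv_counts,
        table.column(hybrid),
        ref,
        table.library_size(hybrid),
        f"MPV({parent_a},{parent_b})",
        hybrid,
        dispersion,
        thresholds,
        **kwargs,
    )
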