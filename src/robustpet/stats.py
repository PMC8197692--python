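"""Per-feature robustness decision procedure.

For each radiomic feature, paired values from two protocols (A, B) over
the same lesions are compared with three complementary analyses:

* Wilcoxon signed-rank test — *robust* means no systematic shift
  (two-sided p > alpha, alpha = 0.05; zero differences dropped).
* Spearman rank correlation — *strongly correlated* means r > 0.8 with
  p below the Bonferroni-corrected level alpha / K, K = number of
  features tested.
* Bland–Altman analysis of pairwise differences relative to pairwise
  means (in %) — *comparable* means the 95% t-CI of the bias contains 0.

The exact Wilcoxon null distribution is enumerated over all 2^n sign
assignments (midranks, so ties are handled) for n <= 12; larger samples
use the normal approximation with tie and continuity corrections.
Spearman p is an exhaustive permutation value for n <= 8, otherwise the
t approximation.

Differences whose magnitude is below a relative tolerance (default 1e-9)
are treated as zero: paired feature values that agree to floating-point
precision carry no evidence of a protocol effect, and sign tests must not
react to rounding noise far below any measurement noise floor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "PairedSample",
    "StatConfig",
    "ComparisonResult",
    "RobustnessReport",
    "wilcoxon_signed_rank",
    "spearman",
    "bland_altman",
    "classify_feature",
    "compare_tables",
    "build_report",
]


@dataclass
class StatConfig:
    """Decision thresholds of the robustness procedure."""

    alpha: float = 0.05
    K: int = 133  # Bonferroni divisor; reset to the tested roster size
    r_threshold: float = 0.8
    min_pairs: int = 5
    exact_wilcoxon_max_n: int = 12
    exact_spearman_max_n: int = 8
    zero_tol_rel: float = 1e-9
    zero_method: str = "drop"  # or "pratt"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or self.K < 1:
            raise ConfigurationError("require 0 < alpha < 1 and K >= 1")
        if self.zero_method not in ("drop", "pratt"):
            raise ConfigurationError("zero_method must be 'drop' or 'pratt'")


@dataclass
class PairedSample:
    """Aligned per-lesion values of one feature under protocols A and B."""

    feature: str
    a: np.ndarray
    b: np.ndarray
    lesion_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ConfigurationError("paired sample arms differ in length")

    @property
    def n(self) -> int:
        return self.a.size


@dataclass
class ComparisonResult:
    """Numeric outcomes + decision flags for one feature, one factor."""

    feature: str
    n: int
    wilcoxon_p: float = math.nan
    spearman_r: float = math.nan
    spearman_p: float = math.nan
    ba_bias_pct: float = math.nan
    ba_ci_95: tuple[float, float] = (math.nan, math.nan)
    ba_loa: tuple[float, float] = (math.nan, math.nan)
    robust: bool = False
    strongly_correlated: bool = False
    ba_comparable: bool = False
    testable: bool = True


def _effective_zeros(d: np.ndarray, a: np.ndarray, b: np.ndarray,
                     rel_tol: float) -> np.ndarray:
    scale = np.maximum(np.abs(a), np.abs(b))
    return np.abs(d) <= rel_tol * np.maximum(scale, 1e-300)


def wilcoxon_signed_rank(
    sample: PairedSample, cfg: StatConfig | None = None
) -> float:
    """Two-sided Wilcoxon signed-rank p for paired arms.

    Exact enumeration of the 2^n sign assignments for n <= 12 (valid with
    ties via midranks); normal approximation with tie and continuity
    correction otherwise.  All-zero differences give p = 1.
    """
    cfg = cfg or StatConfig()
    d = sample.a - sample.b
    zero = _effective_zeros(d, sample.a, sample.b, cfg.zero_tol_rel)
    if cfg.zero_method == "drop":
        d = d[~zero]
    else:  # pratt: rank zeros, then discard their ranks
        d = np.where(zero, 0.0, d)
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    if cfg.zero_method == "pratt":
        keep = d != 0
        ranks, d = ranks[keep], d[keep]
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= cfg.exact_wilcoxon_max_n:
        return _wilcoxon_exact_p(ranks, w_plus)
    mean = ranks.sum() / 2.0
    var = (ranks**2).sum() / 4.0  # midranks embed the tie correction
    if var == 0:
        return 1.0
    z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(2.0 * sps.norm.sf(z))


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    n = ranks.size
    # distribution of W+ over all sign assignments via polynomial rolling
    totals = np.zeros(1)
    totals[0] = 1.0
    scaled = np.round(ranks * 2).astype(int)  # midranks -> integers (x2)
    w2 = int(round(w_plus * 2))
    for r in scaled:
        new = np.zeros(totals.size + r)
        new[: totals.size] += totals
        new[r:] += totals
        totals = new
    total = totals.sum()
    cdf_le = totals[: w2 + 1].sum() / total
    cdf_ge = totals[w2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


def spearman(
    sample: PairedSample, cfg: StatConfig | None = None
) -> tuple[float, float]:
    """Spearman rank correlation (r, two-sided p).

    r is the Pearson correlation of midranks; p is an exhaustive
    permutation value for n <= ``exact_spearman_max_n``, else the t
    approximation.  Constant margins yield (nan, nan).
    """
    cfg = cfg or StatConfig()
    n = sample.n
    ra = sps.rankdata(sample.a)
    rb = sps.rankdata(sample.b)
    if np.all(ra == ra[0]) or np.all(rb == rb[0]):
        return math.nan, math.nan
    r = float(np.corrcoef(ra, rb)[0, 1])
    if n <= cfg.exact_spearman_max_n:
        ra_c = ra - ra.mean()
        rb_c = rb - rb.mean()
        denom = math.sqrt((ra_c**2).sum() * (rb_c**2).sum())
        obs = abs((ra_c * rb_c).sum() / denom)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = rb_c[list(perm)]
            rr = abs((ra_c * rp).sum() / denom)
            count += rr >= obs - 1e-12
            total += 1
        return r, count / total
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, p


def bland_altman(
    sample: PairedSample, cfg: StatConfig | None = None
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Bland–Altman bias of A vs B in percent of the pairwise mean.

    d_i = 100 (a_i - b_i) / ((a_i + b_i)/2); returns (bias, 95% t-CI of
    the bias, limits of agreement bias ± 1.96 SD).  Pairs with zero mean
    are excluded.
    """
    cfg = cfg or StatConfig()
    a, b = sample.a, sample.b
    mean_pair = (a + b) / 2.0
    keep = mean_pair != 0
    if not keep.all():
        import warnings

        warnings.warn(
            f"{sample.feature}: {int((~keep).sum())} zero-mean pairs excluded",
            stacklevel=2,
        )
    a, b, mean_pair = a[keep], b[keep], mean_pair[keep]
    if a.size == 0:
        return math.nan, (math.nan, math.nan), (math.nan, math.nan)
    d = 100.0 * (a - b) / mean_pair
    bias = float(d.mean())
    n = d.size
    sd = float(d.std(ddof=1)) if n > 1 else 0.0
    if n > 1:
        tcrit = float(sps.t.ppf(0.975, df=n - 1))
        half = tcrit * sd / math.sqrt(n)
    else:
        half = 0.0
    ci = (bias - half, bias + half)
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    return bias, ci, loa


def classify_feature(result: ComparisonResult, cfg: StatConfig) -> ComparisonResult:
    """Apply the three decision criteria; flags are pure in the numbers."""
    result.robust = bool(
        result.testable and result.wilcoxon_p > cfg.alpha
    )
    result.strongly_correlated = bool(
        result.testable
        and not math.isnan(result.spearman_r)
        and result.spearman_r > cfg.r_threshold
        and result.spearman_p < cfg.alpha / cfg.K
    )
    lo, hi = result.ba_ci_95
    result.ba_comparable = bool(
        result.testable and not math.isnan(lo) and lo <= 0.0 <= hi
    )
    return result


def compare_feature(sample: PairedSample, cfg: StatConfig) -> ComparisonResult:
    res = ComparisonResult(sample.feature, sample.n)
    if sample.n < cfg.min_pairs:
        res.testable = False
        return classify_feature(res, cfg)
    res.wilcoxon_p = wilcoxon_signed_rank(sample, cfg)
    res.spearman_r, res.spearman_p = spearman(sample, cfg)
    res.ba_bias_pct, res.ba_ci_95, res.ba_loa = bland_altman(sample, cfg)
    return classify_feature(res, cfg)


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    cfg: StatConfig | None = None,
    valid_a: pd.DataFrame | None = None,
    valid_b: pd.DataFrame | None = None,
) -> dict[str, ComparisonResult]:
    """Compare two feature tables (rows = lesions, columns = features).

    Lesion indices must align exactly; degenerate-flagged values (False in
    the ``valid_*`` masks) are excluded pairwise.  K is reset to the
    number of features actually tested.
    """
    cfg = cfg or StatConfig()
    if not table_a.index.equals(table_b.index):
        raise ConfigurationError("lesion IDs of the two protocols do not align")
    if not table_a.columns.equals(table_b.columns):
        raise ConfigurationError("feature columns of the two protocols differ")
    samples = {}
    for feat in table_a.columns:
        ok = np.ones(len(table_a), dtype=bool)
        if valid_a is not None:
            ok &= valid_a[feat].to_numpy()
        if valid_b is not None:
            ok &= valid_b[feat].to_numpy()
        samples[feat] = PairedSample(
            feat,
            table_a.loc[ok, feat].to_numpy(),
            table_b.loc[ok, feat].to_numpy(),
            list(table_a.index[ok]),
        )
    n_testable = sum(s.n >= cfg.min_pairs for s in samples.values())
    cfg = StatConfig(
        alpha=cfg.alpha,
        K=max(n_testable, 1),
        r_threshold=cfg.r_threshold,
        min_pairs=cfg.min_pairs,
        exact_wilcoxon_max_n=cfg.exact_wilcoxon_max_n,
        exact_spearman_max_n=cfg.exact_spearman_max_n,
        zero_tol_rel=cfg.zero_tol_rel,
        zero_method=cfg.zero_method,
    )
    return {f: compare_feature(s, cfg) for f, s in samples.items()}


@dataclass
class RobustnessReport:
    """Per-factor per-feature outcomes plus the cross-factor intersection."""

    factors: dict[str, dict[str, ComparisonResult]] = field(default_factory=dict)

    def robust_set(self, factor: str) -> set[str]:
        return {f for f, r in self.factors[factor].items() if r.robust}

    def correlated_set(self, factor: str) -> set[str]:
        return {f for f, r in self.factors[factor].items() if r.strongly_correlated}

    def intersection(self) -> set[str]:
        sets = [self.robust_set(f) for f in self.factors]
        return set.intersection(*sets) if sets else set()

    def summary(self) -> dict:
        out: dict[str, object] = {}
        for factor in self.factors:
            out[factor] = {
                "n_features": len(self.factors[factor]),
                "n_robust": len(self.robust_set(factor)),
                "n_strongly_correlated": len(self.correlated_set(factor)),
                "n_comparable_ba": sum(
                    r.ba_comparable for r in self.factors[factor].values()
                ),
            }
        out["intersection"] = sorted(self.intersection())
        out["n_intersection"] = len(self.intersection())
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flag matrix (features × factors), the robustness-table analog."""
        feats = sorted({f for res in self.factors.values() for f in res})
        data = {}
        for factor, res in self.factors.items():
            data[f"{factor}_robust"] = [
                res[f].robust if f in res else False for f in feats
            ]
            data[f"{factor}_correlated"] = [
                res[f].strongly_correlated if f in res else False for f in feats
            ]
        return pd.DataFrame(data, index=feats)

    def details_frame(self, factor: str) -> pd.DataFrame:
        rows = []
        for f, r in self.factors[factor].items():
            rows.append({
                "feature": f, "n": r.n, "wilcoxon_p": r.wilcoxon_p,
                "spearman_r": r.spearman_r, "spearman_p": r.spearman_p,
                "ba_bias_pct": r.ba_bias_pct,
                "ba_ci_lo": r.ba_ci_95[0], "ba_ci_hi": r.ba_ci_95[1],
                "robust": r.robust,
                "strongly_correlated": r.strongly_correlated,
                "ba_comparable": r.ba_comparable, "testable": r.testable,
            })
        return pd.DataFrame(rows).set_index("feature")


def build_report(
    tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    cfg: StatConfig | None = None,
    valids: dict[str, tuple[pd.DataFrame, pd.DataFrame]] | None = None,
) -> RobustnessReport:
    """Run the decision procedure for every factor's protocol pair."""
    report = RobustnessReport()
    for factor, (ta, tb) in tables.items():
        va, vb = (valids or {}).get(factor, (None, None))
        report.factors[factor] = compare_tables(ta, tb, cfg, va, vb)
    return report
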