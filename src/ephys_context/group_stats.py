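"""Cross-context population comparisons.

Wilcoxon signed-rank tests on per-unit paired metrics (pooled across
stimuli and per stimulus), with an in-repo step-down Holm-Bonferroni
correction across stimuli for the unpooled family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .session_model import STIMULI
from .spike_metrics import UnitMetrics

MIN_PAIRS = 5
COMPARE_ALPHA = 0.05
#: exact Wilcoxon null up to this many nonzero pairs, normal approx above
EXACT_WILCOXON_MAX_N = 25

METRIC_NAMES = ("z", "offset_z", "fr", "blfr", "d_prime", "offset_ratio")


@dataclass
class ContextComparison:
    metric: str
    stimulus_scope: str          # "pooled" or a stimulus label
    n_units: int
    statistic: Optional[float]
    p_raw: Optional[float]
    p_adjusted: Optional[float]
    significant: Optional[bool]
    note: str = ""


# ---------------------------------------------------------------------------
# primitive tests
# ---------------------------------------------------------------------------

def paired_context_test(values_ctx1: Sequence[float],
                        values_ctx2: Sequence[float]
                        ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired per-unit values.

    Zero differences are dropped (Wilcoxon convention); if everything is a
    zero difference the test degenerates to ``(0.0, 1.0)`` with a warning.
    Exact null distribution for small samples without ties, normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(values_ctx1, float)
    y = np.asarray(values_ctx2, float)
    if x.shape != y.shape:
        raise ValueError("contexts must supply the same units")
    if len(x) < MIN_PAIRS:
        raise ValueError(f"need >= {MIN_PAIRS} pairs, got {len(x)}")
    diffs = x - y
    nonzero = diffs[diffs != 0.0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    no_ties = np.unique(np.abs(nonzero)).size == nonzero.size
    if nonzero.size <= EXACT_WILCOXON_MAX_N and no_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox",
                         correction=(method == "approx"), method=method)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(p_values: Sequence[float], alpha: float = COMPARE_ALPHA
                    ) -> list[tuple[float, bool]]:
    """Step-down Holm correction.

    Sorted ascending, ``p_adj_(i) = max_{j<=i} (m - j + 1) * p_(j)`` capped
    at 1; rejections proceed while ``p_adj < alpha``.  Output is aligned
    with the input order.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    reject = np.zeros(m, bool)
    for rank, idx in enumerate(order):
        if adjusted[idx] < alpha:
            reject[idx] = True
        else:
            break                      # step-down stops at the first failure
    return [(float(a), bool(r)) for a, r in zip(adjusted, reject)]


# ---------------------------------------------------------------------------
# metric extraction
# ---------------------------------------------------------------------------

def _unit_value(m: UnitMetrics, metric: str, stimulus: str,
                context: str) -> Optional[float]:
    if metric == "d_prime":
        if stimulus == "BOS":
            return None                # diagonal is uninformative
        return m.d_prime.get(("BOS", stimulus, context))
    sc = m.per_stimulus.get((stimulus, context))
    if sc is None:
        return None
    return {"z": sc.z, "offset_z": sc.offset_z, "fr": sc.mean_fr_hz,
            "blfr": sc.mean_blfr_hz, "offset_ratio": sc.offset_ratio}[metric]


def _paired_values(metrics: Sequence[UnitMetrics], metric: str,
                   stimuli: Sequence[str], ctx1: str, ctx2: str,
                   dropped_log: dict) -> tuple[list[float], list[float], int]:
    """Pool unit x stimulus pairs defined in both contexts."""
    v1, v2 = [], []
    units = set()
    for m in metrics:
        for stim in stimuli:
            a = _unit_value(m, metric, stim, ctx1)
            b = _unit_value(m, metric, stim, ctx2)
            if a is None or b is None:
                if (a is None) != (b is None):
                    dropped_log["undefined_pairs_dropped"] = \
                        dropped_log.get("undefined_pairs_dropped", 0) + 1
                continue
            v1.append(a)
            v2.append(b)
            units.add(m.unit_id)
    return v1, v2, len(units)


def _dprime_row_average(m: UnitMetrics, context: str) -> Optional[float]:
    """Mean d'(BOS - X) over the non-BOS stimuli (the heatmap's BOS row)."""
    vals = [m.d_prime.get(("BOS", s, context)) for s in STIMULI if s != "BOS"]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# the comparison schema
# ---------------------------------------------------------------------------

def compare_contexts(metrics: Sequence[UnitMetrics],
                     ctx1: str = "solitary", ctx2: str = "social",
                     alpha: float = COMPARE_ALPHA,
                     stimuli: Sequence[str] = STIMULI,
                     exclusion_log: Optional[dict] = None
                     ) -> list[ContextComparison]:
    """One pooled test per metric plus Holm-corrected per-stimulus tests.

    Assumes the SSA/responsiveness filter was applied upstream.  d' uses the
    BOS row: pooled = per-unit average of d'(BOS - X); per-stimulus tests run
    over the non-BOS stimuli.  Comparisons with fewer than 5 common units
    are skipped with a note.
    """
    log = exclusion_log if exclusion_log is not None else {}
    out: list[ContextComparison] = []
    for metric in METRIC_NAMES:
        # ---- pooled ----
        if metric == "d_prime":
            v1 = [_dprime_row_average(m, ctx1) for m in metrics]
            v2 = [_dprime_row_average(m, ctx2) for m in metrics]
            pairs = [(a, b) for a, b in zip(v1, v2)
                     if a is not None and b is not None]
            p1 = [a for a, _ in pairs]
            p2 = [b for _, b in pairs]
            n_units = len(pairs)
        else:
            p1, p2, n_units = _paired_values(metrics, metric, stimuli,
                                             ctx1, ctx2, log)
        out.append(_run_one(metric, "pooled", p1, p2, n_units, alpha,
                            adjust=None))

        # ---- per stimulus, Holm across the family ----
        fam_stims = [s for s in stimuli if not (metric == "d_prime"
                                                and s == "BOS")]
        fam: list[ContextComparison] = []
        for stim in fam_stims:
            p1, p2, n_units = _paired_values(metrics, metric, [stim],
                                             ctx1, ctx2, log)
            fam.append(_run_one(metric, stim, p1, p2, n_units, alpha,
                                adjust=None))
        testable = [c for c in fam if c.p_raw is not None]
        if testable:
            corrected = holm_bonferroni([c.p_raw for c in testable], alpha)
            for c, (p_adj, rej) in zip(testable, corrected):
                c.p_adjusted = p_adj
                c.significant = rej
        out.extend(fam)
    return out


def _run_one(metric: str, scope: str, v1: list, v2: list, n_units: int,
             alpha: float, adjust) -> ContextComparison:
    if n_units < MIN_PAIRS or len(v1) < MIN_PAIRS:
        return ContextComparison(metric, scope, n_units, None, None, None,
                                 None, note="skipped: fewer than "
                                 f"{MIN_PAIRS} common units/pairs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        statistic, p = paired_context_test(v1, v2)
    # pooled comparisons carry no correction; p_adjusted mirrors p_raw
    return ContextComparison(metric, scope, n_units, statistic, p,
                             p, p < alpha)


def comparisons_to_rows(comparisons: Sequence[ContextComparison]
                        ) -> list[dict]:
    return [{"metric": c.metric, "stimulus_scope": c.stimulus_scope,
             "n_units": c.n_units, "statistic": c.statistic,
             "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
             "significant": c.significant, "note": c.note}
            for c in comparisons]
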