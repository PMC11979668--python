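"""Per-patient and aggregated Dice, paired testing, and report tables.

Two Dice flavors are computed per foreground class:

* per-patient DSC, ``2|P∩R| / (|P|+|R|)``;
* aggregated DSC (aggDSC): intersection and mask sizes are pooled over all
  patients *before* forming the ratio, making the score robust to single
  all-miss cases (one empty prediction cannot zero it out the way it zeroes
  a per-case average).

When a class is absent from both prediction and reference the per-case DSC
is defined as 1 and flagged; flagged pairs are excluded from paired testing
by default.  Configurations are compared with a two-sided paired Wilcoxon
signed-rank test at significance level 0.05 (exact null for small samples,
normal approximation with tie correction otherwise).  Scores in report
tables are scaled by 100 with two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .caseio import GeometryError, LabelMap

GTVP, GTVN = 1, 2
FOREGROUND_CLASSES = (GTVP, GTVN)
ALPHA = 0.05
EXACT_N_MAX = 15


@dataclass
class DiceValue:
    value: float
    both_empty: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass
class EvalResult:
    """Per-case and pooled scores for one configuration."""

    per_case: dict[str, dict[str, float]]
    aggregated: dict[str, float]
    n_cases: int
    both_empty_flags: dict[str, dict[str, bool]] = field(default_factory=dict)


def _counts(pred: LabelMap, ref: LabelMap, label: int) -> tuple[int, int, int]:
    if pred.shape != ref.shape:
        raise GeometryError(f"prediction shape {pred.shape} != reference shape {ref.shape}")
    p = pred.labels == label
    r = ref.labels == label
    return int((p & r).sum()), int(p.sum()), int(r.sum())


def dsc(pred: LabelMap, ref: LabelMap, label: int) -> DiceValue:
    """Per-patient Dice for one class; both-empty returns 1 with a flag."""
    inter, np_, nr = _counts(pred, ref, label)
    if np_ + nr == 0:
        return DiceValue(1.0, both_empty=True)
    return DiceValue(2.0 * inter / (np_ + nr))


def agg_dsc(pairs: list[tuple[LabelMap, LabelMap]], label: int) -> DiceValue:
    """Pooled Dice across cases: 2·Σ|Pᵢ∩Rᵢ| / (Σ|Pᵢ| + Σ|Rᵢ|)."""
    if not pairs:
        raise ValueError("agg_dsc needs at least one (pred, ref) pair")
    inter = size = 0
    for pred, ref in pairs:
        i, np_, nr = _counts(pred, ref, label)
        inter += i
        size += np_ + nr
    if size == 0:
        return DiceValue(1.0, both_empty=True)
    return DiceValue(2.0 * inter / size)


def evaluate_cases(
    preds: dict[str, LabelMap], refs: dict[str, LabelMap]
) -> EvalResult:
    """Score a configuration over a named case set."""
    missing = sorted(set(refs) ^ set(preds))
    if missing:
        raise ValueError(f"prediction/reference case sets differ: {missing}")
    per_case, flags = {}, {}
    pairs = []
    for cid in sorted(refs):
        pred, ref = preds[cid], refs[cid]
        dp = dsc(pred, ref, GTVP)
        dn = dsc(pred, ref, GTVN)
        per_case[cid] = {
            "DSC_GTVp": dp.value,
            "DSC_GTVn": dn.value,
            "mean_DSC": (dp.value + dn.value) / 2.0,
        }
        flags[cid] = {"DSC_GTVp": dp.both_empty, "DSC_GTVn": dn.both_empty}
        pairs.append((pred, ref))
    ap = agg_dsc(pairs, GTVP)
    an = agg_dsc(pairs, GTVN)
    aggregated = {
        "aggDSC_GTVp": ap.value,
        "aggDSC_GTVn": an.value,
        "avg_aggDSC": (ap.value + an.value) / 2.0,
    }
    return EvalResult(per_case, aggregated, len(pairs), flags)


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False
    n_effective: int = 0


def _exact_two_sided_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided signed-rank p over all 2^n sign assignments.

    Uses the generating function of the positive-rank sum (doubled midranks
    keep everything integral under ties): p = P(W ≤ lo) + P(W ≥ hi) for the
    observed statistic and its mirror.  Returns (W+, p).
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    poly = np.zeros(total + 1)
    poly[0] = 1.0
    for r in r2:
        nxt = poly.copy()
        nxt[r:] += poly[: total + 1 - r]
        poly = nxt
    w_plus = float(ranks[d > 0].sum())
    w2 = int(round(2 * w_plus))
    lo, hi = min(w2, total - w2), max(w2, total - w2)
    p = (poly[: lo + 1].sum() + poly[hi:].sum()) / 2 ** len(r2)
    return w_plus, min(1.0, float(p))


def wilcoxon_paired(a, b, alpha: float = ALPHA) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; the exact null distribution (enumerated,
    ties handled through midranks) is used for n ≤ 15 effective pairs,
    otherwise scipy's normal approximation with tie correction.  All-zero
    differences return a degenerate, non-significant result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return WilcoxonResult(0.0, 1.0, False, degenerate=True, n_effective=0)
    if nz.size <= EXACT_N_MAX:
        stat, p = _exact_two_sided_p(nz)
    else:
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                             method="approx", correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return WilcoxonResult(
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha),
        n_effective=int(nz.size),
    )


def count_islands(pred: LabelMap, prior: LabelMap) -> int:
    """Connected components of predicted foreground disjoint from the prior mask.

    The qualitative artifact of mask-sampled training followed by
    unrestricted inference: spurious components outside the prior region.
    26-connectivity.
    """
    fg = pred.labels > 0
    prior_fg = prior.labels > 0
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(fg, structure=structure)
    islands = 0
    for c in range(1, n + 1):
        if not (prior_fg & (comp == c)).any():
            islands += 1
    return islands


def boxplot_per_case(
    results: dict[str, EvalResult],
    path,
    starred: set[str] | frozenset[str] = frozenset(),
    scale: float = 100.0,
) -> None:
    """Box plot of per-patient mean DSC per configuration.

    Configurations in ``starred`` (significantly different from the best)
    get an asterisk appended to their label.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, data = [], []
    for name, res in results.items():
        labels.append(f"{name} *" if name in starred else name)
        data.append([scale * s["mean_DSC"] for s in res.per_case.values()])
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(data), 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("per-patient mean DSC")
    ax.set_ylim(0, scale * 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def per_case_table(results: dict[str, EvalResult]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        for cid, scores in res.per_case.items():
            rows.append({"config": name, "case_id": cid, **scores})
    return pd.DataFrame(rows)


def report(
    results: dict[str, "EvalResult | tuple[EvalResult, EvalResult]"],
    best_epochs: dict[str, int] | None = None,
    comparisons: list[tuple[str, str]] | None = None,
    alpha: float = ALPHA,
    scale: float = 100.0,
) -> dict[str, pd.DataFrame]:
    """Assemble best/final aggDSC and per-case significance tables.

    ``results`` maps a configuration name to either one EvalResult (used for
    both columns) or a (best, final) pair.  ``comparisons`` lists
    (config, reference_config) pairs to test; a star marks configurations
    whose per-case mean DSC differs significantly from the reference.
    """
    best_epochs = best_epochs or {}
    agg_rows = []
    finals: dict[str, EvalResult] = {}
    for name, res in results.items():
        best, final = res if isinstance(res, tuple) else (res, res)
        finals[name] = final
        agg_rows.append(
            {
                "config": name,
                "best_GTVp": round(scale * best.aggregated["aggDSC_GTVp"], 2),
                "best_GTVn": round(scale * best.aggregated["aggDSC_GTVn"], 2),
                "best_avg": round(scale * best.aggregated["avg_aggDSC"], 2),
                "best_epoch": best_epochs.get(name, ""),
                "final_GTVp": round(scale * final.aggregated["aggDSC_GTVp"], 2),
                "final_GTVn": round(scale * final.aggregated["aggDSC_GTVn"], 2),
                "final_avg": round(scale * final.aggregated["avg_aggDSC"], 2),
            }
        )
    agg_table = pd.DataFrame(agg_rows)

    case_sets = {name: set(r.per_case) for name, r in finals.items()}
    ref_set = None
    for name, cs in case_sets.items():
        if ref_set is None:
            ref_set = cs
        elif cs != ref_set:
            raise ValueError(
                f"configuration {name!r} has a different case set: "
                f"{sorted(cs ^ ref_set)}"
            )

    sig_rows = []
    for name, ref_name in comparisons or []:
        ra, rb = finals[name], finals[ref_name]
        cids = sorted(ra.per_case)
        a = [ra.per_case[c]["mean_DSC"] for c in cids]
        b = [rb.per_case[c]["mean_DSC"] for c in cids]
        w = wilcoxon_paired(a, b, alpha=alpha)
        sig_rows.append(
            {
                "config": name,
                "vs": ref_name,
                "mean_DSC": round(scale * float(np.mean(a)), 2),
                "p_value": w.p_value,
                "star": "*" if w.significant else "",
            }
        )
    sig_table = pd.DataFrame(sig_rows)
    return {"aggdsc": agg_table, "significance": sig_table, "per_case": per_case_table(finals)}
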