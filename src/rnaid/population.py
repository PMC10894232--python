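"""Population-level summaries of sized translocation events.

Aggregates per-event results into the quantities a transcription-termination
study reports: mean +/- SD transcript length per termination class, counts
by transcription cycle, termination efficiency PT/(PT+END), the linear
ECD-versus-duration relation, length histograms, and the geometric decay of
cycle counts from which the per-cycle continuation probability of the
polymerase is estimated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import linregress

from .sizing import TERM_END, TERM_ORIC

__all__ = [
    "PopulationSummary",
    "CycleDecayFit",
    "summarize_classes",
    "ecd_time_regression",
    "termination_efficiency",
    "cycle_decay",
    "truncated_geometric_loglik",
    "plot_population",
]


@dataclass
class PopulationSummary:
    class_stats: pd.DataFrame      # index: termination class; columns n, mean_kbp, sd_kbp, se_kbp
    cycle_counts: pd.Series        # index: n_cycles, values: counts (sized events)
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    n_sized: int


def summarize_classes(sized: pd.DataFrame, bin_width_kbp: float = 0.1) -> PopulationSummary:
    """Per-class length statistics and an overall length histogram.

    Expects columns ``length_kbp``, ``termination_class`` and ``n_cycles``;
    rows without a finite length (unclassifiable events) are excluded from
    the statistics.  Means carry the sample SD (and SE) per class.
    """
    if len(sized) == 0:
        warnings.warn("no sized events to summarize", stacklevel=2)
        empty = pd.DataFrame(columns=["n", "mean_kbp", "sd_kbp", "se_kbp"])
        return PopulationSummary(empty, pd.Series(dtype=int), np.array([0.0]), np.array([]), 0)
    ok = sized[np.isfinite(sized["length_kbp"])]
    rows = {}
    for cls, grp in ok.groupby("termination_class"):
        x = grp["length_kbp"].to_numpy()
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows[cls] = {
            "n": int(x.size),
            "mean_kbp": float(np.mean(x)),
            "sd_kbp": sd,
            "se_kbp": sd / math.sqrt(x.size) if x.size else math.nan,
        }
    class_stats = pd.DataFrame.from_dict(rows, orient="index")
    cycle_counts = ok["n_cycles"].value_counts().sort_index()
    if len(ok):
        top = float(ok["length_kbp"].max())
        edges = np.arange(0.0, top + 2 * bin_width_kbp, bin_width_kbp)
        counts, edges = np.histogram(ok["length_kbp"], bins=edges)
    else:
        edges, counts = np.array([0.0]), np.array([])
    return PopulationSummary(class_stats, cycle_counts, edges, counts, int(len(ok)))


def ecd_time_regression(
    durations_ms: np.ndarray | pd.Series, ecds_fC: np.ndarray | pd.Series
) -> tuple[float, float, float]:
    """OLS of event charge deficit on translocation time.

    Returns ``(slope fC/ms, intercept fC, Pearson r)``; the relation is
    linear for a homogeneous translocation population.
    """
    d = np.asarray(durations_ms, dtype=float)
    e = np.asarray(ecds_fC, dtype=float)
    if d.size < 3:
        raise ValueError(f"regression needs at least 3 events, got {d.size}")
    fit = linregress(d, e)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def termination_efficiency(sized_or_counts) -> float:
    """Fraction of OriC-terminated transcripts among PT + END products.

    Accepts a sized-event DataFrame (column ``termination_class``) or a
    mapping of class name to count.  Raises on a zero denominator.
    """
    if isinstance(sized_or_counts, pd.DataFrame):
        counts = sized_or_counts["termination_class"].value_counts().to_dict()
    else:
        counts = dict(sized_or_counts)
    pt = counts.get(TERM_ORIC, 0)
    end = counts.get(TERM_END, 0)
    if pt + end == 0:
        raise ValueError("no PT or END events: termination efficiency undefined")
    return pt / (pt + end)


@dataclass
class CycleDecayFit:
    q_hat: float                     # per-cycle continuation probability
    n_total: int
    n_max: int
    last_censored: bool
    loglik: float
    expected_counts: dict[int, float]


def truncated_geometric_loglik(
    counts: Mapping[int, int], q: float, last_censored: bool = False
) -> float:
    """Log-likelihood of cycle counts under the geometric continuation model.

    ``last_censored=True`` treats events at the largest observed cycle as
    right-censored (they were stopped by the modelling cap, not observed to
    terminate); otherwise the geometric law is renormalized over 1..N.
    """
    n_max = max(n for n, c in counts.items() if c > 0)
    total = sum(counts.values())
    if not 0.0 <= q < 1.0:
        return -math.inf
    ll = 0.0
    for n, c in counts.items():
        if c == 0:
            continue
        if last_censored and n == n_max:
            ll += c * (n - 1) * (math.log(q) if q > 0 else (-math.inf if n > 1 else 0.0))
        else:
            if q == 0.0:
                ll += c * (math.log(1.0) if n == 1 else -math.inf)
            else:
                ll += c * ((n - 1) * math.log(q) + math.log(1.0 - q))
    if not last_censored and q > 0:
        ll -= total * math.log(1.0 - q**n_max)
    return ll


def cycle_decay(
    counts: Mapping[int, int] | pd.Series, last_censored: bool = False
) -> CycleDecayFit:
    """ML estimate of the per-cycle continuation probability q.

    Under the geometric termination model an event stops after each cycle
    independently with probability ``1 - q``; observed cycle counts then
    decay as ``q**(n-1)``.  The default fit renormalizes the law over the
    observed support 1..N (e.g. counts 100/50/25 give exactly q = 0.5);
    with ``last_censored=True`` events at N are treated as censored by the
    modelling cap, the correct likelihood for generator output.
    """
    if isinstance(counts, pd.Series):
        counts = {int(k): int(v) for k, v in counts.items()}
    else:
        counts = {int(k): int(v) for k, v in counts.items()}
    if any(n < 1 for n in counts):
        raise ValueError("cycle counts must be indexed by n >= 1")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no events in cycle counts")
    n_max = max(n for n, c in counts.items() if c > 0)
    s = sum(c * (n - 1) for n, c in counts.items())

    if s == 0:
        q_hat = 0.0
    elif last_censored:
        c_last = counts.get(n_max, 0)
        denom = s + total - c_last
        q_hat = 1.0 if denom == 0 else s / denom
    else:
        def score(q: float) -> float:
            return (
                s / q
                - total / (1.0 - q)
                + total * n_max * q ** (n_max - 1) / (1.0 - q**n_max)
            )

        lo, hi = 1e-12, 1.0 - 1e-9
        if score(hi) > 0:          # counts do not decay: boundary solution
            q_hat = hi
        else:
            q_hat = float(brentq(score, lo, hi))

    expected: dict[int, float] = {}
    for n in range(1, n_max + 1):
        if last_censored and n == n_max:
            expected[n] = total * q_hat ** (n - 1)
        elif q_hat >= 1.0:
            expected[n] = 0.0
        else:
            p = q_hat ** (n - 1) * (1.0 - q_hat)
            if not last_censored:
                p /= 1.0 - q_hat**n_max
            expected[n] = total * p
    ll = truncated_geometric_loglik(counts, min(q_hat, 1.0 - 1e-12), last_censored)
    return CycleDecayFit(q_hat, total, n_max, last_censored, ll, expected)


def plot_population(events: pd.DataFrame, sized: pd.DataFrame, out_prefix) -> list[str]:
    """Write the standard population figures (ECD-vs-time scatter, length
    histogram colored by cycle count).  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    written = []
    kept = events[events["kept"]] if "kept" in events else events
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(kept["duration_ms"], kept["ecd_fC"], s=12, alpha=0.6)
    ax.set_xlabel("translocation time (ms)")
    ax.set_ylabel("event charge deficit (fC)")
    fig.tight_layout()
    p = f"{out_prefix}_ecd_vs_time.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    ok = sized[np.isfinite(sized["length_kbp"])]
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(ok):
        for n, grp in ok.groupby("n_cycles"):
            ax.hist(grp["length_kbp"], bins=np.arange(0, ok["length_kbp"].max() + 0.2, 0.1),
                    alpha=0.6, label=f"n = {n}", density=True)
        ax.legend(frameon=False)
    ax.set_xlabel("sized length (kbp)")
    ax.set_ylabel("normalized count")
    fig.tight_layout()
    p = f"{out_prefix}_length_hist.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
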