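"""Reference study simulations: seeded fixture runs and their headline numbers.

These functions reproduce the package's headline population results from
scratch: they simulate the packaged construct fixtures at the default study
conditions, run the full analysis pipeline on the raw synthetic trace, and
report the population quantities (class mean lengths, termination
efficiency, modal lengths per cycle count).  They are used by the
acceptance tests and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import load_fixture
from .pipeline import analyze_trace
from .population import termination_efficiency
from .simulate import SimParams, simulate_trace
from .sizing import TERM_END, TERM_ORIC

__all__ = ["linear_recovery_study", "circular_recovery_study", "modal_length"]


def modal_length(lengths_kbp: pd.Series | np.ndarray, bin_width_kbp: float = 0.1) -> float:
    """Mode of a binned length histogram: center of the fullest bin."""
    x = np.asarray(lengths_kbp, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no lengths to histogram")
    edges = np.arange(0.0, x.max() + 2 * bin_width_kbp, bin_width_kbp)
    counts, edges = np.histogram(x, bins=edges)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def linear_recovery_study(seed: int, n_events: int = 500) -> dict:
    """Simulate unfolded linear-fixture events and size them end to end.

    Returns the mean sized length (kbp) and count of PT- and END-classified
    events plus the estimated termination efficiency.
    """
    design, sim = load_fixture("linear")
    params = SimParams(seed=seed, p_fold=0.0).with_overrides(sim)
    trace, _ = simulate_trace(design, params, n_events)
    result = analyze_trace(trace, design)
    ok = result.sized.dropna(subset=["length_kbp"])
    out: dict = {"n_events": n_events, "n_sized": int(len(ok))}
    for key, cls in (("pt", TERM_ORIC), ("end", TERM_END)):
        grp = ok[ok["termination_class"] == cls]["length_kbp"]
        out[f"{key}_mean_kbp"] = float(grp.mean())
        out[f"{key}_sd_kbp"] = float(grp.std(ddof=1))
        out[f"{key}_n"] = int(len(grp))
    out["termination_efficiency"] = float(termination_efficiency(result.sized))
    return out


def circular_recovery_study(seed: int, n_events: int = 600) -> dict:
    """Simulate circular-fixture events (rolling circle, low dissociation)
    and report the modal sized length of OriC-terminated events per cycle
    count n = 1..3."""
    design, sim = load_fixture("circular")
    params = SimParams(seed=seed).with_overrides(sim)
    trace, _ = simulate_trace(design, params, n_events)
    result = analyze_trace(trace, design)
    oric = result.sized[result.sized["termination_class"] == TERM_ORIC]
    out: dict = {"n_events": n_events, "n_oric": int(len(oric))}
    for n in (1, 2, 3):
        grp = oric[oric["n_cycles"] == n]["length_kbp"]
        out[f"mode_n{n}_kbp"] = modal_length(grp)
        out[f"count_n{n}"] = int(len(grp))
    return out
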