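"""Event-level statistics on ssDNA/dsDNA hybrid substrates.

Binding events on force-melted DNA tethers are classified by substrate
(dsDNA, RPA-covered ssDNA tract, or the ssDNA-dsDNA junction within the
diffraction limit of a tract edge), compared against the available length
of each substrate class via a log2 enrichment, and summarized with exact
contingency tests, bootstrap protection fractions, binding-position
histograms and compaction rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "classify_binding_events",
    "substrate_availability",
    "log2_enrichment",
    "fisher_exact",
    "protection_fraction",
    "position_histogram",
    "compaction_rate",
]

CLASSES = ("dsDNA", "ssDNA", "junction")


def classify_binding_events(
    positions: np.ndarray,
    tracts: list[tuple[float, float]],
    junction_window: float = 0.3,
) -> np.ndarray:
    """Assign each binding position to dsDNA, ssDNA, or junction.

    An event within ``junction_window`` (um; default 300 nm, roughly the
    diffraction limit) of the nearest tract edge is a junction event;
    otherwise it is ssDNA if inside a tract and dsDNA if outside.
    """
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    out = np.full(positions.shape, "dsDNA", dtype=object)
    if tracts:
        edges = np.array([e for t in tracts for e in t], dtype=float)
        for i, x in enumerate(positions):
            if np.min(np.abs(edges - x)) <= junction_window:
                out[i] = "junction"
            elif any(lo <= x <= hi for lo, hi in tracts):
                out[i] = "ssDNA"
    return out


def _merge(intervals):
    ivs = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    merged = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return merged


def _total_len(intervals):
    return sum(hi - lo for lo, hi in intervals)


def _subtract(intervals, cut):
    out = []
    for lo, hi in intervals:
        segs = [(lo, hi)]
        for clo, chi in cut:
            nxt = []
            for a, b in segs:
                if chi <= a or clo >= b:
                    nxt.append((a, b))
                else:
                    if a < clo:
                        nxt.append((a, clo))
                    if chi < b:
                        nxt.append((chi, b))
            segs = nxt
        out.extend(segs)
    return out


def substrate_availability(
    tracts: list[tuple[float, float]],
    total_length: float,
    junction_window: float = 0.3,
) -> dict:
    """Fraction of tether length available per substrate class.

    Each tract edge contributes a junction band of width 2*junction_window
    (the window on either side of the edge), clipped to the tether and
    merged on overlap; the band length is removed from the flanking ssDNA
    and dsDNA classes so the three availabilities sum to 1.
    """
    if total_length <= 0:
        raise ValueError("total_length must be > 0")
    tr = _merge([(max(lo, 0.0), min(hi, total_length)) for lo, hi in tracts])
    edges = [e for t in tr for e in t if 0.0 < e < total_length]
    bands = _merge(
        [(max(e - junction_window, 0.0), min(e + junction_window, total_length))
         for e in edges]
    )
    a_j = _total_len(bands) / total_length
    a_ss = _total_len(_subtract(tr, bands)) / total_length
    return {"dsDNA": 1.0 - a_ss - a_j, "ssDNA": a_ss, "junction": a_j}


def log2_enrichment(x: dict, a: dict) -> pd.DataFrame:
    """log2E = log2(x) - log2(a) per class: observed event fraction over
    available substrate fraction.  Classes with zero observed fraction are
    reported as -inf and flagged."""
    rows = []
    for cls in x:
        xv, av = x[cls], a[cls]
        with np.errstate(divide="ignore"):
            le = np.log2(xv) - np.log2(av) if av > 0 else np.nan
        rows.append({"class": cls, "x": xv, "a": av, "log2E": le,
                     "degenerate": not np.isfinite(le)})
    return pd.DataFrame(rows)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (p_value, odds_ratio).  Two-sided p sums the hypergeometric
    probabilities of all tables (with the observed margins) no more likely
    than the observed one, the minimum-likelihood convention.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), float(odds)


def protection_fraction(
    table: dict,
    B: int = 2000,
    level: float = 0.68,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Protected fraction per flanking-occupancy category with bootstrap CI.

    ``table`` maps category (e.g. 0, 1, 2 occupied tract termini) to
    (n_protected, n_total).  The interval is a percentile case bootstrap
    over the Bernoulli outcomes; for 0-of-n or n-of-n the band collapses
    one-sidedly at the boundary.
    """
    rng = np.random.default_rng(seed)
    rows = []
    qlo, qhi = (1 - level) / 2, (1 + level) / 2
    for cat, (k, n) in table.items():
        if not 0 <= k <= n:
            raise ValueError("need 0 <= n_protected <= n_total")
        frac = k / n
        outcomes = np.concatenate([np.ones(k), np.zeros(n - k)])
        boots = rng.choice(outcomes, size=(B, n), replace=True).mean(axis=1)
        rows.append({"category": cat, "n_protected": k, "n_total": n,
                     "fraction": frac,
                     "lo": float(np.quantile(boots, qlo)),
                     "hi": float(np.quantile(boots, qhi))})
    return pd.DataFrame(rows)


def position_histogram(
    positions: np.ndarray,
    substrate_length: float | None = None,
    n_bins: int = 20,
    B: int = 1000,
    level: float = 0.68,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Binding-position histogram with bootstrap confidence intervals.

    Positions are normalized to the substrate length (fraction in [0, 1]);
    counts per bin sum to n.
    """
    x = np.asarray(positions, dtype=float)
    if substrate_length is not None:
        x = x / substrate_length
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(x, 0, 1), bins=edges)
    rng = np.random.default_rng(seed)
    boot = np.empty((B, n_bins))
    for b in range(B):
        xb = rng.choice(x, size=len(x), replace=True)
        boot[b], _ = np.histogram(np.clip(xb, 0, 1), bins=edges)
    qlo, qhi = (1 - level) / 2, (1 + level) / 2
    return pd.DataFrame({
        "bin_center": 0.5 * (edges[:-1] + edges[1:]),
        "count": counts,
        "density": counts / len(x) * n_bins if len(x) else np.zeros(n_bins),
        "lo": np.quantile(boot, qlo, axis=0),
        "hi": np.quantile(boot, qhi, axis=0),
    })


def compaction_rate(times: np.ndarray, lengths: np.ndarray) -> tuple[float, float]:
    """Compaction rate (um/s) and compacted fraction from a length series.

    The monotone compaction interval runs from the (smoothed) maximum
    length to the subsequent minimum; the rate is the magnitude of a
    robust Theil-Sen slope over that interval, and the compacted fraction
    is 1 - final/initial.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if len(t) != len(y) or len(t) < 2:
        raise ValueError("need matched series of length >= 2")
    win = max(1, min(5, len(y) // 4))
    ys = pd.Series(y).rolling(win, center=True, min_periods=1).mean().to_numpy()
    i0 = int(np.argmax(ys))
    i1 = i0 + int(np.argmin(ys[i0:]))
    if i1 <= i0:
        return 0.0, 0.0
    seg_t, seg_y = t[i0:i1 + 1], y[i0:i1 + 1]
    if len(seg_t) >= 3:
        slope = stats.theilslopes(seg_y, seg_t)[0]
    else:
        slope = (seg_y[-1] - seg_y[0]) / (seg_t[-1] - seg_t[0])
    initial, final = ys[i0], ys[i1]
    rate = max(-slope, 0.0)
    fraction = 1.0 - final / initial if initial > 0 else 0.0
    return float(rate), float(max(fraction, 0.0))
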