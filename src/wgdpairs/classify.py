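"""Classification of candidate pairs as WGD-retained duplicates.

A pair is WGD-retained when its 4DTV falls inside the configured window
(default 0.04-0.2, endpoints inclusive) and the two copies are not tandem
duplicates (same chromosome with an interval gap strictly within the
distance threshold, default 100 kb).  The window is applied to the raw
transversion proportion by default; the corrected value is carried alongside
and the metric is configurable — the correction is monotone, so a window on
one scale maps to a window on the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .divergence import DivergenceEstimates
from .io import Position


@dataclass
class ClassifiedPair:
    pair_id: str
    id_a: str
    id_b: str
    four_dtv_raw: float | None
    four_dtv_corr: float | None
    in_window: bool
    is_tandem: bool
    wgd_retained: bool
    chrom_a: str | None = None
    chrom_b: str | None = None
    distance_bp: int | None = None  # same-chromosome interval gap
    note: str = ""


def window_classify(value: float | None, low: float = 0.04, high: float = 0.2
                    ) -> bool:
    """In-window iff ``low <= value <= high`` (both endpoints inclusive);
    undefined values are never in-window."""
    if low >= high:
        raise ValueError("window low must be < high")
    if value is None:
        return False
    return low <= value <= high


def interval_gap(a: Position, b: Position) -> int | None:
    """Gap in bp between two gene intervals on the same chromosome (0 when
    they touch or overlap); ``None`` for different chromosomes."""
    if a.chromosome != b.chromosome:
        return None
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end)


def tandem_filter(pos_a: Position | None, pos_b: Position | None,
                  max_dist: int = 100_000) -> tuple[bool, int | None, str]:
    """(is_tandem, distance_bp, note).  Tandem iff both copies are placed on
    the same chromosome with an interval gap strictly below ``max_dist``
    ("within"); unplaced copies are never tandem, with a note."""
    if pos_a is None or pos_b is None:
        return False, None, "unplaced"
    gap = interval_gap(pos_a, pos_b)
    if gap is None:
        return False, None, ""
    return gap < max_dist, gap, ""


def classify_pairs(estimates: list[DivergenceEstimates],
                   positions: dict[str, Position],
                   dtv_low: float = 0.04, dtv_high: float = 0.2,
                   tandem_max_bp: int = 100_000,
                   window_metric: str = "raw") -> list[ClassifiedPair]:
    """Apply the 4DTV window and the tandem proximity filter to every pair."""
    if window_metric not in {"raw", "corrected"}:
        raise ValueError(f"unknown window metric {window_metric!r}")
    out = []
    for est in estimates:
        value = est.four_dtv_raw if window_metric == "raw" else est.four_dtv_corr
        in_window = window_classify(value, dtv_low, dtv_high)
        pos_a = positions.get(est.id_a)
        pos_b = positions.get(est.id_b)
        is_tandem, gap, note = tandem_filter(pos_a, pos_b, tandem_max_bp)
        out.append(ClassifiedPair(
            pair_id=est.pair_id, id_a=est.id_a, id_b=est.id_b,
            four_dtv_raw=est.four_dtv_raw, four_dtv_corr=est.four_dtv_corr,
            in_window=in_window, is_tandem=is_tandem,
            wgd_retained=in_window and not is_tandem,
            chrom_a=pos_a.chromosome if pos_a else None,
            chrom_b=pos_b.chromosome if pos_b else None,
            distance_bp=gap, note=note,
        ))
    return out


def classified_to_frame(classified: list[ClassifiedPair]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in classified])


def chromosome_pairing_summary(classified: list[ClassifiedPair],
                               wgd_only: bool = True
                               ) -> tuple[pd.DataFrame, float | None]:
    """Symmetric chromosome x chromosome count matrix over placed pairs plus
    the fraction of placed pairs whose copies lie on different chromosomes
    (unplaced pairs are excluded from the denominator)."""
    pool = [c for c in classified if (c.wgd_retained or not wgd_only)]
    placed = [c for c in pool if c.chrom_a and c.chrom_b]
    chroms = sorted({c.chrom_a for c in placed} | {c.chrom_b for c in placed})
    mat = pd.DataFrame(0, index=chroms, columns=chroms, dtype=int)
    n_diff = 0
    for c in placed:
        mat.loc[c.chrom_a, c.chrom_b] += 1
        if c.chrom_a != c.chrom_b:
            mat.loc[c.chrom_b, c.chrom_a] += 1
            n_diff += 1
    frac = n_diff / len(placed) if placed else None
    return mat, frac


def dtv_histogram(estimates: list[DivergenceEstimates], bin_width: float = 0.01,
                  metric: str = "raw") -> pd.DataFrame:
    """Histogram of the 4DTV distribution (for eyeballing the WGD peak the
    window should bracket)."""
    attr = "four_dtv_raw" if metric == "raw" else "four_dtv_corr"
    values = [getattr(e, attr) for e in estimates if getattr(e, attr) is not None]
    if not values:
        return pd.DataFrame(columns=["bin_low", "bin_high", "count"])
    top = max(values) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({
        "bin_low": edges[:-1].round(10),
        "bin_high": edges[1:].round(10),
        "count": counts,
    })


def cascade_counts(classified: list[ClassifiedPair]) -> dict[str, int]:
    """Filtering-cascade tallies; by construction
    n_in_window = n_tandem_in_window + n_wgd_retained."""
    n_in = sum(c.in_window for c in classified)
    n_tandem_in = sum(c.in_window and c.is_tandem for c in classified)
    n_wgd = sum(c.wgd_retained for c in classified)
    return {
        "n_candidates": len(classified),
        "n_in_window": n_in,
        "n_out_of_window": len(classified) - n_in,
        "n_tandem_in_window": n_tandem_in,
        "n_wgd_retained": n_wgd,
    }
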