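"""m6A levels on chromatin RNA: IP/input ratios, cross-condition log2 ratios,
linker-histone quartile analysis, and peak window classification.

The m6A level of a transcript is the depth-normalized MeRIP (IP) read count
over the extended transcript interval [TSS - 2 kb, TTS + 2 kb) divided by the
matching chromatin-RNA input signal over the same extent.  Genes missing in
either replicate are excluded before replicate means are taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, GeneSet, window


@dataclass
class MethylationRecord:
    gene_id: str
    ip_signal: float | None
    input_signal: float | None
    level: float | None  # IP/input; None when undefined
    condition: str = ""
    n_replicates_used: int = 0


def m6a_level(
    ip_counts: Mapping[int, float | None],
    input_counts: Mapping[int, float | None],
    ip_totals: Mapping[int, float],
    input_totals: Mapping[int, float],
    g: GeneModel,
    condition: str = "",
) -> MethylationRecord:
    """Replicate-mean depth-normalized IP/input ratio for one gene.

    ``ip_counts``/``input_counts`` map replicate -> read count over the
    extended transcript interval (None = gene absent in that replicate).  A
    gene missing in any replicate is excluded (level None); a zero input
    signal also yields an undefined level.
    """
    reps = sorted(ip_totals)
    if any(t <= 0 for t in ip_totals.values()) or any(
        t <= 0 for t in input_totals.values()
    ):
        raise ValueError("totals must be > 0")
    present = [
        r
        for r in reps
        if ip_counts.get(r) is not None and input_counts.get(r) is not None
    ]
    if len(present) < len(reps):
        return MethylationRecord(g.gene_id, None, None, None, condition, len(present))
    ip_norm = [ip_counts[r] / ip_totals[r] * 1e6 for r in reps]
    in_norm = [input_counts[r] / input_totals[r] * 1e6 for r in reps]
    levels = [i / j for i, j in zip(ip_norm, in_norm) if j > 0]
    ip_mean = float(np.mean(ip_norm))
    in_mean = float(np.mean(in_norm))
    if len(levels) < len(reps):
        return MethylationRecord(g.gene_id, ip_mean, in_mean, None, condition, len(reps))
    return MethylationRecord(
        g.gene_id, ip_mean, in_mean, float(np.mean(levels)), condition, len(reps)
    )


def m6a_table(
    merip: pd.DataFrame,
    genes: GeneSet,
    totals: Mapping[tuple[str, str, int], float],
) -> pd.DataFrame:
    """Per-gene, per-condition m6A levels from a tidy MeRIP count table.

    ``merip`` has columns gene_id, condition, replicate, ip_count,
    input_count; ``totals`` maps (assay, condition, replicate) -> total
    aligned reads where assay is 'merip_ip' or 'merip_input'.
    """
    rows = []
    for (gid, cond), sub in merip.groupby(["gene_id", "condition"], sort=True):
        if gid not in genes:
            continue
        reps = sorted(sub["replicate"].unique())
        ipc = {int(r["replicate"]): r["ip_count"] for _, r in sub.iterrows()}
        inc = {int(r["replicate"]): r["input_count"] for _, r in sub.iterrows()}
        ip_tot = {r: totals[("merip_ip", cond, r)] for r in reps}
        in_tot = {r: totals[("merip_input", cond, r)] for r in reps}
        rec = m6a_level(ipc, inc, ip_tot, in_tot, genes[gid], cond)
        rows.append(
            {
                "gene_id": gid,
                "condition": cond,
                "ip_signal": rec.ip_signal,
                "input_signal": rec.input_signal,
                "level": rec.level,
                "n_replicates_used": rec.n_replicates_used,
            }
        )
    return pd.DataFrame(rows)


def m6a_condition_ratio(
    tko: MethylationRecord, wt: MethylationRecord
) -> float | None:
    """log2(TKO level / WT level); None when either level is undefined or 0."""
    if tko.level is None or wt.level is None or tko.level <= 0 or wt.level <= 0:
        return None
    return math.log2(tko.level / wt.level)


def _quartile_labels(values: np.ndarray) -> np.ndarray:
    """Quartile labels 1..4 with type-7 boundaries; boundary ties go lower."""
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    labels = np.full(len(values), 4, dtype=int)
    labels[values <= q3] = 3
    labels[values <= q2] = 2
    labels[values <= q1] = 1
    return labels


def h1_quartile_ratio_analysis(
    h1_occupancy: Mapping[str, float],
    ratios: Mapping[str, float],
) -> pd.DataFrame:
    """Cross-condition m6A log2 ratios across quartiles of H1 occupancy.

    Genes with both a promoter-proximal H1 signal and a defined log2 ratio
    are split into 4 quartiles by H1 occupancy; per quartile, the median
    ratio and the one-sample Wilcoxon signed-rank p-value against 0 are
    reported (degenerate all-zero quartiles report p = 1 by convention).
    """
    common = sorted(set(h1_occupancy) & set(ratios))
    common = [g for g in common if ratios[g] is not None]
    if len(common) < 8:
        raise ValueError("need at least 8 genes with both measurements")
    h1 = np.array([h1_occupancy[g] for g in common])
    rr = np.array([ratios[g] for g in common], dtype=float)
    labels = _quartile_labels(h1)
    rows = []
    for q in (1, 2, 3, 4):
        vals = rr[labels == q]
        if len(vals) == 0:
            raise ValueError(f"empty quartile {q}")
        if np.allclose(vals, 0):
            p = 1.0
            stat = 0.0
        else:
            res = stats.wilcoxon(vals, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "quartile": q,
                "n": len(vals),
                "median_log2_ratio": float(np.median(vals)),
                "wilcoxon_stat": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def classify_peak_windows(
    peaks: Sequence[tuple[str, int, int]],
    genes: GeneSet,
    speed_classes: Mapping[str, str] | None = None,
    halfwidth: int = 2000,
) -> pd.DataFrame:
    """Classify m6A peaks into TSS/TTS +/- 2 kb windows per speed class.

    A peak is assigned to a gene when its midpoint falls inside the extended
    interval [TSS - 2 kb, TTS + 2 kb); its class is decided by the midpoint:
    TSS if within TSS +/- 2 kb, TTS if within TTS +/- 2 kb, 'both' when the
    windows overlap (short genes), else 'neither'.  Returns per-speed-class
    fractions.
    """
    assignments = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, start, end in peaks:
        mid = (start + end) // 2
        hit = None
        for g in by_chrom.get(chrom, []):
            s, e, _ = window(g, "TSS", halfwidth, g.length + halfwidth)
            if s <= mid < e:
                hit = g
                break
        if hit is None:
            continue
        ts, te, _ = window(hit, "TSS", halfwidth, halfwidth)
        es, ee, _ = window(hit, "TTS", halfwidth, halfwidth)
        in_tss = ts <= mid < te
        in_tts = es <= mid < ee
        cls = (
            "both" if in_tss and in_tts
            else "TSS" if in_tss
            else "TTS" if in_tts
            else "neither"
        )
        speed = (speed_classes or {}).get(hit.gene_id, "all")
        assignments.append({"speed_class": speed, "window_class": cls})
    if not assignments:
        return pd.DataFrame(
            columns=["speed_class", "window_class", "n", "fraction"]
        )
    df = pd.DataFrame(assignments)
    out = (
        df.groupby(["speed_class", "window_class"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = out.groupby("speed_class")["n"].transform("sum")
    out["fraction"] = out["n"] / totals
    return out
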