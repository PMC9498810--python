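"""Spike-in-corrected RNAPII occupancy, pausing index, CheRNA output, and
MNase fragment preprocessing.

Dual-genome spike-in normalization: human chromatin is added to mouse samples
before immunoprecipitation, so the mouse/human aligned-read ratio tracks the
global IP yield.  The correction factor for a TKO sample is

    factor = (mouseWT / humanWT) / (mouseTKO / humanTKO)

and the spike-in-normalized TKO signal is the reads-normalized signal
multiplied by this factor.  Occupancies are RPKM-like: reads per kb of region
per million total aligned reads, times the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd


class SpikeInError(ValueError):
    """Fatal spike-in ledger problem (zero totals)."""


@dataclass
class SpikeInLedger:
    """Per-sample mouse/human aligned-read totals.

    Samples are keyed by (condition, replicate); counts must be positive.
    """

    samples: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)

    def add(self, condition: str, replicate: int, mouse_reads: int, human_reads: int) -> None:
        if mouse_reads <= 0 or human_reads <= 0:
            raise SpikeInError(
                f"non-positive read totals for {condition} rep {replicate}"
            )
        self.samples[(condition, replicate)] = (int(mouse_reads), int(human_reads))

    def mouse(self, condition: str, replicate: int) -> int:
        return self.samples[(condition, replicate)][0]

    def human(self, condition: str, replicate: int) -> int:
        return self.samples[(condition, replicate)][1]

    def replicates(self, condition: str) -> list[int]:
        return sorted(r for c, r in self.samples if c == condition)

    def to_json(self, path: str | Path) -> None:
        d = {f"{c}:{r}": v for (c, r), v in self.samples.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpikeInLedger":
        d = json.loads(Path(path).read_text())
        led = cls()
        for key, (m, h) in d.items():
            c, r = key.rsplit(":", 1)
            led.add(c, int(r), m, h)
        return led


def spike_in_factor(
    mouse_wt: float, human_wt: float, mouse_tko: float, human_tko: float
) -> float:
    """Correction factor (mouseWT/humanWT) / (mouseTKO/humanTKO)."""
    if min(mouse_wt, human_wt, mouse_tko, human_tko) <= 0:
        raise SpikeInError("all four read totals must be > 0")
    return (mouse_wt / human_wt) / (mouse_tko / human_tko)


def spike_in_factors(
    ledger: SpikeInLedger, reference: str = "WT", target: str = "TKO"
) -> dict[int, float]:
    """Per-replicate correction factors pairing target with reference samples."""
    out = {}
    for rep in ledger.replicates(target):
        if (reference, rep) not in ledger.samples:
            raise SpikeInError(f"no {reference} sample for replicate {rep}")
        out[rep] = spike_in_factor(
            ledger.mouse(reference, rep),
            ledger.human(reference, rep),
            ledger.mouse(target, rep),
            ledger.human(target, rep),
        )
    return out


def region_occupancy(counts, region_len, total_reads, factor: float = 1.0):
    """RPKM-like normalized signal: count / (kb of region) / (M total reads).

    ``factor`` is the spike-in correction (1 for the reference condition).
    Accepts scalars or numpy arrays.
    """
    region_len = np.asarray(region_len, dtype=float)
    if np.any(region_len <= 0):
        raise ValueError("region_len must be > 0")
    if np.any(np.asarray(total_reads, dtype=float) <= 0):
        raise ValueError("total_reads must be > 0")
    return (
        np.asarray(counts, dtype=float)
        / (region_len / 1000.0)
        / (np.asarray(total_reads, dtype=float) / 1e6)
        * factor
    )


def pausing_index(promoter, body):
    """Promoter / gene-body occupancy ratio; NaN (excluded) when body = 0."""
    promoter = np.asarray(promoter, dtype=float)
    body = np.asarray(body, dtype=float)
    if np.any(promoter < 0) or np.any(body < 0):
        raise ValueError("occupancies must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(body > 0, promoter / np.where(body > 0, body, 1.0), np.nan)
    return out if out.ndim else float(out)


def cherna_output(counts_by_replicate, transcript_len, totals_by_replicate):
    """Replicate-mean RPKM-like chromatin-RNA output per gene.

    ``counts_by_replicate`` and ``totals_by_replicate`` are sequences aligned
    by replicate; counts may be arrays over genes.
    """
    per_rep = [
        region_occupancy(c, transcript_len, t)
        for c, t in zip(counts_by_replicate, totals_by_replicate)
    ]
    return np.mean(per_rep, axis=0)


def pausing_table(
    chip: pd.DataFrame,
    genes,
    ledger: SpikeInLedger,
    reference: str = "WT",
    target: str = "TKO",
    promoter_halfwidth: int = 500,
) -> pd.DataFrame:
    """Replicate-mean promoter/body occupancies and pausing index per gene.

    ``chip`` has columns gene_id, condition, replicate, promoter_count,
    body_count.  Totals are the ledger's mouse read counts; target-condition
    signals are multiplied by the per-replicate spike-in factor.  The pausing
    index is computed from replicate-mean signals; genes with zero body signal
    get NaN and are excluded from downstream statistics.
    """
    factors = spike_in_factors(ledger, reference, target)
    lens = {g.gene_id: g.length for g in genes}
    rows = []
    for (gid, cond), sub in chip.groupby(["gene_id", "condition"], sort=True):
        if gid not in lens:
            continue
        body_len = max(lens[gid] - promoter_halfwidth, 1)
        prom_vals, body_vals = [], []
        for _, r in sub.iterrows():
            rep = int(r["replicate"])
            total = ledger.mouse(cond, rep)
            fac = factors[rep] if cond == target else 1.0
            prom_vals.append(
                region_occupancy(r["promoter_count"], 2 * promoter_halfwidth, total, fac)
            )
            body_vals.append(region_occupancy(r["body_count"], body_len, total, fac))
        prom = float(np.mean(prom_vals))
        body = float(np.mean(body_vals))
        rows.append(
            {
                "gene_id": gid,
                "condition": cond,
                "promoter": prom,
                "body": body,
                "pausing_index": pausing_index(prom, body),
            }
        )
    return pd.DataFrame(rows)


def mnase_fragment_filter(
    pairs: pd.DataFrame,
    max_span: int = 250,
    trim: int = 25,
) -> pd.DataFrame:
    """Mononucleosomal fragment preprocessing.

    Keeps pairs whose mates map the same chromosome with fragment span
    strictly below ``max_span`` bp, trims ``trim`` bp at both ends, and drops
    fragments whose trimmed length is <= 0.  Expects columns chrom, start,
    end (and optionally chrom2 for the mate's chromosome).
    """
    df = pairs.copy()
    if "chrom2" in df.columns:
        df = df[df["chrom"] == df["chrom2"]]
    span = df["end"] - df["start"]
    df = df[span < max_span]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"] + trim,
            "end": df["end"] - trim,
        }
    )
    out = out[out["end"] - out["start"] > 0]
    return out.reset_index(drop=True)
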