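"""Synthetic DRB/4sU time-course and count-table generator with known truth.

The generator emulates the study design end-to-end so every downstream stage
is testable without sequencing data:

* a transcription wave released from the TSS at t = 0 that advances at a
  per-gene rate ``v`` (kb/min), observed through a 4sU pulse of
  ``label_window`` minutes: labeled fragment 5' ends are uniform on the
  trailing segment ``[max(0, v*(t - label_window)), v*t]`` kb from the TSS,
  clipped to the gene body;
* an exon-restricted background emulating mature-mRNA contamination, present
  at every time point (t = 0 emits background only);
* Poisson sampling of fragment counts at configurable depth;
* ChIP promoter/body, chromatin-RNA (CheRNA) and MeRIP IP/input count tables
  with a dual-genome spike-in ledger whose mouse totals are scaled so that
  the spike-in correction factor recovers ``spike_in_true_factor``.

All outputs are deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneSet
from .chip import SpikeInLedger

# Rate models: a plain float (constant), or ("bimodal", (mode1, mode2),
# (weight1, weight2), sigma_log).  The default mirrors the observed mixture of
# a slow (< 2 kb/min) and a dominant fast (~3.5 kb/min) component, with about
# one third of genes in the slow component.
DEFAULT_RATE_MODEL = ("bimodal", (2.0, 3.5), (1 / 3, 2 / 3), 0.15)
# m6A enrichment models: float, ("groups", values) assigned cyclically, or
# ("lognormal", mean_log, sigma_log).
DEFAULT_M6A_MODEL = ("groups", (0.5, 1.0, 2.0, 4.0))


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults follow the experimental design being emulated: a 0/5-minute
    DRB-release series with a 10-minute 4sU pulse, two replicates, two
    conditions, genes of 30-60 kb, 2000 labeled fragments and 100 exonic
    background fragments expected per gene per time point.
    """

    n_genes: int = 300
    gene_length_range: tuple[int, int] = (30_000, 60_000)
    rate_model: object = DEFAULT_RATE_MODEL
    time_points: tuple[float, ...] = (0.0, 5.0)
    label_window: float = 10.0
    depth: float = 2000.0
    background: float = 100.0
    n_replicates: int = 2
    conditions: tuple[str, ...] = ("WT", "TKO")
    spike_in_true_factor: float = 1.0
    m6a_enrichment_model: object = DEFAULT_M6A_MODEL
    fragment_length: int = 75
    genes_per_chrom: int = 50
    intergenic_gap: int = 10_000
    chip_total_reads: float = 1_000_000.0
    human_spike_fraction: float = 0.05  # 1/20th human chromatin added
    cherna_total_reads: float = 1_000_000.0
    merip_total_reads: float = 100_000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise SimulationError("n_genes must be > 0")
        lo, hi = self.gene_length_range
        if lo < 1000 or hi < lo:
            raise SimulationError("gene_length_range must be >= 1 kb and ordered")
        if self.depth <= 0 or self.background < 0:
            raise SimulationError("depth must be > 0 and background >= 0")
        if self.n_replicates <= 0:
            raise SimulationError("n_replicates must be > 0")
        if self.spike_in_true_factor <= 0:
            raise SimulationError("spike_in_true_factor must be > 0")
        if self.label_window <= 0:
            raise SimulationError("label_window must be > 0")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=list))


@dataclass
class GroundTruth:
    """Per-gene and per-condition true values keyed like the emitted GeneSet."""

    rates: dict[str, float] = field(default_factory=dict)  # kb/min
    m6a_ratio: dict[str, float] = field(default_factory=dict)  # IP/input
    spike_in_factor: dict[str, float] = field(default_factory=dict)  # per condition
    promoter_occupancy: dict[str, float] = field(default_factory=dict)  # RPKM scale
    body_occupancy: dict[str, float] = field(default_factory=dict)  # RPKM scale
    cherna_output: dict[str, float] = field(default_factory=dict)  # RPKM scale

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *stream])


def simulate_annotation(cfg: SimulationConfig) -> GeneSet:
    """Place non-overlapping genes on synthetic chromosomes.

    Genes get 2-10 exons of 150-400 bp each, lengths uniform in
    ``gene_length_range``, alternating random strands, 50 genes per
    chromosome separated by 10-kb gaps.  Deterministic under ``seed``.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    lo, hi = cfg.gene_length_range
    gs = GeneSet(provenance=f"simulated, n={cfg.n_genes}, seed={cfg.seed}")
    pos = cfg.intergenic_gap
    chrom_idx = 1
    for i in range(cfg.n_genes):
        if i > 0 and i % cfg.genes_per_chrom == 0:
            chrom_idx += 1
            pos = cfg.intergenic_gap
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        n_ex = int(rng.integers(2, 11))
        # one exon per equal-length segment keeps them sorted & non-overlapping
        seg = length // n_ex
        exons = []
        for k in range(n_ex):
            ex_len = int(rng.integers(150, 401))
            ex_len = min(ex_len, seg - 1)
            off = int(rng.integers(0, seg - ex_len))
            exons.append((start + k * seg + off, start + k * seg + off + ex_len))
        tss, tts = (start, end) if strand == "+" else (end, start)
        gs.add(
            GeneModel(
                gene_id=f"g{i:04d}",
                chrom=f"synth{chrom_idx}",
                strand=strand,
                tss=tss,
                tts=tts,
                exons=tuple(exons),
            )
        )
        pos = end + cfg.intergenic_gap
    return gs


def _draw_rates(rng: np.random.Generator, n: int, model: object) -> np.ndarray:
    if isinstance(model, (int, float)):
        return np.full(n, float(model))
    kind = model[0]
    if kind == "constant":
        return np.full(n, float(model[1]))
    if kind == "bimodal":
        _, modes, weights, sigma = model
        comp = rng.choice(len(modes), size=n, p=np.asarray(weights) / np.sum(weights))
        return np.exp(rng.normal(np.log(np.asarray(modes))[comp], sigma))
    if kind == "uniform":
        return rng.uniform(model[1], model[2], size=n)
    raise SimulationError(f"unknown rate model {model!r}")


def _draw_m6a(rng: np.random.Generator, n: int, model: object) -> np.ndarray:
    if isinstance(model, (int, float)):
        return np.full(n, float(model))
    kind = model[0]
    if kind == "groups":
        vals = np.asarray(model[1], dtype=float)
        return vals[np.arange(n) % len(vals)]
    if kind == "lognormal":
        return np.exp(rng.normal(model[1], model[2], size=n))
    raise SimulationError(f"unknown m6a model {model!r}")


def make_ground_truth(genes: GeneSet, cfg: SimulationConfig) -> GroundTruth:
    """Draw per-gene true rates, m6A ratios and occupancies."""
    cfg.validate()
    rng = _rng(cfg, 1)
    ids = [g.gene_id for g in genes]
    n = len(ids)
    rates = _draw_rates(rng, n, cfg.rate_model)
    if np.any(rates <= 0):
        raise SimulationError("rate model produced non-positive rates")
    m6a = _draw_m6a(rng, n, cfg.m6a_enrichment_model)
    promoter = np.exp(rng.normal(np.log(50.0), 0.5, size=n))
    pausing = np.exp(rng.normal(np.log(5.0), 0.5, size=n))
    body = promoter / pausing
    cherna = np.exp(rng.normal(np.log(10.0), 0.7, size=n))
    truth = GroundTruth(
        rates=dict(zip(ids, rates.tolist())),
        m6a_ratio=dict(zip(ids, m6a.tolist())),
        spike_in_factor={c: (1.0 if c == "WT" else cfg.spike_in_true_factor)
                         for c in cfg.conditions},
        promoter_occupancy=dict(zip(ids, promoter.tolist())),
        body_occupancy=dict(zip(ids, body.tolist())),
        cherna_output=dict(zip(ids, cherna.tolist())),
    )
    return truth


def _exonic_positions(g: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative exon lengths and exon starts, for uniform exonic draws."""
    starts = np.array([s for s, _ in g.exons])
    lens = np.array([e - s for s, e in g.exons])
    return starts, lens


def simulate_wave(
    genes: GeneSet,
    truth: GroundTruth,
    t: float,
    cfg: SimulationConfig,
    replicate: int = 0,
    condition: str = "WT",
) -> pd.DataFrame:
    """Fragment table (chrom, start, end, gene_id) for one time point.

    For t > 0, labeled fragment 5' ends per gene are uniform on the 4sU-labeled
    trailing wave segment ``[max(0, v*(t - label_window)), v*t]`` kb from the
    TSS, clipped to the gene body, with Poisson(depth) counts.  An independent
    exon-restricted background with Poisson(background) counts is added at all
    time points; t = 0 emits background only.
    """
    cfg.validate()
    if t not in cfg.time_points:
        raise SimulationError(f"time point {t} not in config {cfg.time_points}")
    cond_idx = cfg.conditions.index(condition)
    rng = _rng(cfg, 2, int(round(t * 1000)), replicate, cond_idx)
    rows_chrom: list[np.ndarray] = []
    chroms: list[str] = []
    starts_all: list[np.ndarray] = []
    ids_all: list[str] = []
    frames = []
    for g in genes:
        v = truth.rates[g.gene_id]  # kb/min
        tpos = np.empty(0)
        if t > 0:
            lo = max(0.0, v * (t - cfg.label_window)) * 1000.0
            hi = min(v * t * 1000.0, float(g.length))
            lo = min(lo, float(g.length))
            if hi > lo:
                n_sig = rng.poisson(cfg.depth)
                tpos = rng.uniform(lo, hi, size=n_sig)
        # exonic background at all time points
        n_bg = rng.poisson(cfg.background) if cfg.background > 0 else 0
        if n_bg > 0:
            ex_starts, ex_lens = _exonic_positions(g)
            cum = np.concatenate([[0], np.cumsum(ex_lens)])
            u = rng.uniform(0, cum[-1], size=n_bg)
            which = np.searchsorted(cum, u, side="right") - 1
            bg_genomic = ex_starts[which] + (u - cum[which])
            bg_t = np.array([g.to_transcript_coord(int(p)) for p in bg_genomic])
            tpos = np.concatenate([tpos, bg_t])
        if len(tpos) == 0:
            continue
        tpos = np.floor(tpos).astype(int)
        # transcript coord -> genomic 5' end; fragment extends 3' in
        # transcription direction
        if g.strand == "+":
            gstart = g.tss + tpos
            gend = gstart + cfg.fragment_length
        else:
            g5 = g.tss - 1 - tpos
            gstart = g5 - cfg.fragment_length + 1
            gend = g5 + 1
        frames.append(
            pd.DataFrame(
                {
                    "chrom": g.chrom,
                    "start": np.maximum(gstart, 0),
                    "end": gend,
                    "gene_id": g.gene_id,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "gene_id"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


@dataclass
class CountTables:
    """Simulated count tables plus the spike-in ledger and per-sample totals."""

    chip: pd.DataFrame  # gene_id, condition, replicate, promoter_count, body_count
    cherna: pd.DataFrame  # gene_id, condition, replicate, count
    merip: pd.DataFrame  # gene_id, condition, replicate, ip_count, input_count
    ledger: SpikeInLedger
    totals: pd.DataFrame  # assay, condition, replicate, total_reads


def simulate_count_tables(
    genes: GeneSet, truth: GroundTruth, cfg: SimulationConfig
) -> CountTables:
    """ChIP promoter/body, CheRNA and MeRIP IP/input counts with spike-ins.

    Counts are Poisson around the truth; TKO mouse totals in the ledger are
    scaled by 1/spike_in_true_factor so the dual-genome correction factor
    recovers the configured truth in expectation.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    ids = [g.gene_id for g in genes]
    prom_kb = 1.0  # TSS +/- 500 bp
    body_kb = np.array([max(g.length - 500, 1) / 1000.0 for g in genes])
    extent_kb = np.array([(g.length + 4000) / 1000.0 for g in genes])
    tx_kb = np.array([g.length / 1000.0 for g in genes])
    prom_truth = np.array([truth.promoter_occupancy[i] for i in ids])
    body_truth = np.array([truth.body_occupancy[i] for i in ids])
    cherna_truth = np.array([truth.cherna_output[i] for i in ids])
    m6a_truth = np.array([truth.m6a_ratio[i] for i in ids])

    ledger = SpikeInLedger()
    chip_rows, cherna_rows, merip_rows, totals_rows = [], [], [], []
    human_total = cfg.chip_total_reads * cfg.human_spike_fraction
    for cond in cfg.conditions:
        f = truth.spike_in_factor[cond]
        mouse_total_exp = cfg.chip_total_reads / f
        for rep in range(1, cfg.n_replicates + 1):
            mouse_reads = int(rng.poisson(mouse_total_exp))
            human_reads = int(rng.poisson(human_total))
            ledger.add(cond, rep, mouse_reads, human_reads)
            # expected counts invert the downstream RPKM+factor normalization,
            # so corrected occupancies recover the truth in expectation
            scale = (mouse_total_exp / 1e6) / f
            prom_counts = rng.poisson(prom_truth * prom_kb * scale)
            body_counts = rng.poisson(body_truth * body_kb * scale)
            chip_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": ids,
                        "condition": cond,
                        "replicate": rep,
                        "promoter_count": prom_counts,
                        "body_count": body_counts,
                    }
                )
            )
            totals_rows.append(("chip", cond, rep, mouse_reads))

            cherna_counts = rng.poisson(
                cherna_truth * tx_kb * cfg.cherna_total_reads / 1e6
            )
            cherna_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": ids,
                        "condition": cond,
                        "replicate": rep,
                        "count": cherna_counts,
                    }
                )
            )
            totals_rows.append(("cherna", cond, rep, int(cfg.cherna_total_reads)))

            input_exp = np.full(len(ids), cfg.merip_total_reads / len(ids))
            ip_exp = m6a_truth * input_exp
            merip_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": ids,
                        "condition": cond,
                        "replicate": rep,
                        "ip_count": rng.poisson(ip_exp),
                        "input_count": rng.poisson(input_exp),
                    }
                )
            )
            totals_rows.append(("merip_ip", cond, rep, int(cfg.merip_total_reads)))
            totals_rows.append(("merip_input", cond, rep, int(cfg.merip_total_reads)))
    return CountTables(
        chip=pd.concat(chip_rows, ignore_index=True),
        cherna=pd.concat(cherna_rows, ignore_index=True),
        merip=pd.concat(merip_rows, ignore_index=True),
        ledger=ledger,
        totals=pd.DataFrame(
            totals_rows, columns=["assay", "condition", "replicate", "total_reads"]
        ),
    )


def fragments_to_bedgraph(frags: pd.DataFrame, path: str | Path) -> None:
    """Write fragment-interval coverage as a bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom, sub in frags.groupby("chrom", sort=True):
            lo = int(sub["start"].min())
            hi = int(sub["end"].max())
            delta = np.zeros(hi - lo + 1, dtype=np.int64)
            np.add.at(delta, sub["start"].to_numpy() - lo, 1)
            np.add.at(delta, sub["end"].to_numpy() - lo, -1)
            cov = np.cumsum(delta)[:-1]
            # run-length encode
            change = np.flatnonzero(np.diff(cov)) + 1
            bounds = np.concatenate([[0], change, [len(cov)]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if cov[a] != 0:
                    fh.write(f"{chrom}\t{lo + a}\t{lo + b}\t{cov[a]}\n")


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    """TSV fragment table writer (chrom, start, end, gene_id)."""
    frags.to_csv(path, sep="\t", index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a TSV fragment table as written by :func:`write_fragments`."""
    return pd.read_csv(path, sep="\t")
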