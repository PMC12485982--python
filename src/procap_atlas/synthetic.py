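"""Synthetic PRO-cap dataset generator with known ground truth.

Emulates the data structure of a nascent-transcription atlas at the level
downstream analyses consume: strand-specific per-base 5'/3'-end counts,
element intervals with divergent two-strand geometry, negative-binomial
element counts with tissue-specific activity, peaked/broad positional read
distributions, and per-molecule pause offsets between 5' and 3' ends.

The generator is the test bed for every pipeline stage: its outputs carry
an :class:`ElementTruth` table (geometry, directionality, proximity, shape
labels, tissue activity, pause means) so parameter recovery can be checked
end to end.  Sequence content is deliberately absent — there is no FASTA,
no motifs; everything is count geometry.

Model summary
-------------
* Element count per sample ~ NegativeBinomial(mean = activity(element,
  tissue) x sample size factor, size = ``nb_dispersion``).  Divergent
  elements draw each strand independently at half the mean.
* Tissue-specific elements are ON (``baseline_mean x fold_change``) in
  their active tissue and near-silent (``baseline_mean x off_level``)
  elsewhere; non-specific elements sit at ``baseline_mean`` everywhere.
* 5' positions within an element are peaked (two-sided geometric decay
  from the summit, success probability ``peaked_decay``) or broad
  (uniform over the strand peak span).
* Each read's 3' end is the 5' end plus a pause offset drawn from
  Normal(element pause mean, ``pause_sd``) truncated at 0, signed by
  strand.
* Uniform background reads are added genome-wide at ``background_rate``
  reads per kb per strand.
* Sample size factors are log-uniform in [0.5, 2] so normalization has a
  planted signal to recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneAnnotation, GenomicInterval, ReadPairTable, SignalTrack, write_bedgraph
from .elements import Element, Peak

__all__ = ["TruthConfig", "ElementTruth", "SimulatedDataset", "simulate_dataset",
           "simulate_count_matrix", "degrade_library", "write_dataset",
           "simulate_origin_study", "OriginStudy"]

DEFAULT_TISSUES = {"liver": 3, "brain": 3, "lung": 3, "heart": 3}
PAUSE_REGIMES = ((25.0, 5.0), (50.0, 5.0), (90.0, 5.0))


@dataclass
class TruthConfig:
    """Generator parameters; defaults are the study conditions of the suite."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 30
    gene_length: int = 10_000
    n_elements: int = 60
    frac_divergent: float = 0.7
    divergent_gap: tuple[int, int] = (80, 300)  # summit separation, sampled uniformly
    frac_proximal: float = 0.3
    peak_halfwidth: int = 100  # strand peak span = 2*halfwidth + 1
    tissues: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    baseline_mean: float = 100.0
    nb_dispersion: float = 50.0  # NB size; 1/size is the DESeq2-style alpha
    specific_frac: float = 0.3
    fold_change: float = 8.0
    off_level: float = 0.2  # basal activity of specific elements outside their tissue
    frac_peaked: float = 0.5
    peaked_decay: float = 0.5  # geometric success prob; higher = sharper summit
    pause_regimes: Sequence[tuple[float, float]] = PAUSE_REGIMES
    background_rate: float = 0.1  # reads per kb per strand per sample
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_divergent", "frac_proximal", "specific_frac", "frac_peaked"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_elements", "gene_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.divergent_gap
        if lo < 0 or hi < lo:
            raise ValueError("divergent_gap must be 0 <= lo <= hi")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not 0 < self.peaked_decay <= 1:
            raise ValueError("peaked_decay must be in (0, 1]")


@dataclass
class ElementTruth:
    """Planted ground truth for one element."""

    element_id: str
    interval: GenomicInterval
    directionality: str  # divergent | unidirectional
    proximity: str  # proximal | distal
    shape_plus: str | None  # P | B | None (strand absent)
    shape_minus: str | None
    plus_summit: int | None
    minus_summit: int | None
    activity: dict[str, float]  # tissue -> expected per-sample mean (both strands)
    pause_mean: float


@dataclass
class SimulatedDataset:
    config: TruthConfig
    genes: GeneAnnotation
    truth: list[ElementTruth]
    elements: list[Element]
    design: pd.DataFrame  # sample_id, tissue
    size_factors: pd.Series  # planted per-sample factors
    tracks5: dict[str, SignalTrack]
    tracks3: dict[str, SignalTrack]
    pairs: dict[str, ReadPairTable]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = {
                "element_id": t.element_id,
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "directionality": t.directionality,
                "proximity": t.proximity,
                "shape_plus": t.shape_plus,
                "shape_minus": t.shape_minus,
                "pause_mean": t.pause_mean,
            }
            row.update({f"activity_{k}": v for k, v in t.activity.items()})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _place_genes(cfg: TruthConfig, rng: np.random.Generator) -> GeneAnnotation:
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chroms)
    spacing = cfg.chrom_length // (per_chrom + 1)
    if spacing < cfg.gene_length + 20_000:
        raise ValueError("chromosomes too short for the requested gene count")
    records = []
    gid = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for i in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            start = spacing * (i + 1) - cfg.gene_length // 2
            strand = "+" if gid % 2 == 0 else "-"
            records.append((f"gene{gid:04d}", chrom, start, start + cfg.gene_length, strand))
            gid += 1
    return GeneAnnotation.from_records(records)


def _element_geometry(cfg: TruthConfig, genes: GeneAnnotation, rng: np.random.Generator):
    """Place element anchors: proximal ones at gene TSSs, distal ones in gaps."""
    n_prox = int(round(cfg.frac_proximal * cfg.n_elements))
    if n_prox > len(genes):
        raise ValueError(
            f"cannot place {n_prox} proximal elements with only {len(genes)} genes"
        )
    gdf = genes.df
    prox_genes = rng.choice(len(gdf), size=n_prox, replace=False)
    anchors: list[tuple[str, int, str]] = []  # chrom, anchor pos, proximity
    for gi in prox_genes:
        tss = int(gdf.iloc[gi]["tss"])
        anchors.append((gdf.iloc[gi]["chrom"], tss + int(rng.integers(-100, 101)), "proximal"))
    # distal slots: midway through intergenic gaps, >= 3 kb from any gene
    slots: list[tuple[str, int]] = []
    margin = 3_000
    step = 2_500
    for chrom, sub in gdf.groupby("chrom"):
        sub = sub.sort_values("start")
        bounds = [0, *sub["start"].tolist(), cfg.chrom_length]
        ends = [0, *sub["end"].tolist()]
        for prev_end, next_start in zip(ends, bounds[1:]):
            lo, hi = prev_end + margin, next_start - margin
            slots.extend((chrom, p) for p in range(lo, hi, step))
    n_dist = cfg.n_elements - n_prox
    if n_dist > len(slots):
        raise ValueError("not enough intergenic space for the requested distal elements")
    chosen = rng.choice(len(slots), size=n_dist, replace=False)
    anchors.extend((slots[i][0], slots[i][1], "distal") for i in sorted(chosen))
    return anchors


def _build_truth(cfg: TruthConfig, genes: GeneAnnotation, rng: np.random.Generator):
    anchors = _element_geometry(cfg, genes, rng)
    tissues = list(cfg.tissues)
    truth: list[ElementTruth] = []
    elements: list[Element] = []
    n_div = int(round(cfg.frac_divergent * len(anchors)))
    divergent_flags = np.zeros(len(anchors), dtype=bool)
    divergent_flags[rng.choice(len(anchors), size=n_div, replace=False)] = True
    specific_flags = np.zeros(len(anchors), dtype=bool)
    n_spec = int(round(cfg.specific_frac * len(anchors)))
    specific_flags[rng.choice(len(anchors), size=n_spec, replace=False)] = True
    hw = cfg.peak_halfwidth
    for idx, (chrom, anchor, proximity) in enumerate(anchors):
        eid = f"el{idx:04d}"
        if divergent_flags[idx]:
            gap = int(rng.integers(cfg.divergent_gap[0], cfg.divergent_gap[1] + 1))
            minus_summit = anchor - gap // 2
            plus_summit = minus_summit + gap
            start = minus_summit - hw
            end = plus_summit + hw + 1
            shape_p = "P" if rng.random() < cfg.frac_peaked else "B"
            shape_m = "P" if rng.random() < cfg.frac_peaked else "B"
            directionality = "divergent"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            summit = anchor
            plus_summit = summit if strand == "+" else None
            minus_summit = summit if strand == "-" else None
            start, end = summit - hw, summit + hw + 1
            shape_p = ("P" if rng.random() < cfg.frac_peaked else "B") if strand == "+" else None
            shape_m = ("P" if rng.random() < cfg.frac_peaked else "B") if strand == "-" else None
            directionality = "unidirectional"
        if start < 0 or end > cfg.chrom_length:
            raise ValueError("element geometry exceeds chromosome bounds")
        if specific_flags[idx]:
            active = tissues[int(rng.integers(len(tissues)))]
            activity = {
                t: cfg.baseline_mean * (cfg.fold_change if t == active else cfg.off_level)
                for t in tissues
            }
        else:
            activity = {t: cfg.baseline_mean for t in tissues}
        mu, _sd = cfg.pause_regimes[int(rng.integers(len(cfg.pause_regimes)))]
        truth.append(
            ElementTruth(
                element_id=eid,
                interval=GenomicInterval(chrom, start, end),
                directionality=directionality,
                proximity=proximity,
                shape_plus=shape_p,
                shape_minus=shape_m,
                plus_summit=plus_summit,
                minus_summit=minus_summit,
                activity=activity,
                pause_mean=mu,
            )
        )
        plus_peak = (
            Peak(GenomicInterval(chrom, plus_summit - hw, plus_summit + hw + 1, "+"),
                 summit=plus_summit, count=1)
            if plus_summit is not None else None
        )
        minus_peak = (
            Peak(GenomicInterval(chrom, minus_summit - hw, minus_summit + hw + 1, "-"),
                 summit=minus_summit, count=1)
            if minus_summit is not None else None
        )
        elements.append(
            Element(
                element_id=eid,
                span=GenomicInterval(chrom, start, end),
                directionality=directionality,
                plus_peak=plus_peak,
                minus_peak=minus_peak,
                proximity=proximity,
            )
        )
    return truth, elements


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: float, size_param: float, n: int = 1) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n, dtype=np.int64)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n)


def _sample_5p_positions(
    rng: np.random.Generator, n: int, summit: int, span: GenomicInterval, shape: str,
    decay: float,
) -> np.ndarray:
    if shape == "B":
        return rng.integers(span.start, span.end, size=n)
    offsets = rng.geometric(decay, size=n) - 1
    signs = rng.choice((-1, 1), size=n)
    pos = summit + signs * offsets
    return np.clip(pos, span.start, span.end - 1)


def _pause_offsets(rng: np.random.Generator, n: int, mu: float, sd: float) -> np.ndarray:
    return np.maximum(np.rint(rng.normal(mu, sd, size=n)), 0).astype(np.int64)


def simulate_dataset(config: TruthConfig) -> SimulatedDataset:
    """Generate a full dataset: tracks, read pairs, design, and ground truth.

    Bit-reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _place_genes(config, rng)
    truth, elements = _build_truth(config, genes, rng)

    samples: list[tuple[str, str]] = []
    for tissue, n in config.tissues.items():
        for r in range(n):
            samples.append((f"{tissue}_{r + 1}", tissue))
    design = pd.DataFrame(samples, columns=["sample_id", "tissue"])
    sf = pd.Series(
        np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples))),
        index=design["sample_id"],
        name="size_factor",
    )

    tracks5: dict[str, SignalTrack] = {}
    tracks3: dict[str, SignalTrack] = {}
    pairs: dict[str, ReadPairTable] = {}
    pause_sd = {mu: sd for mu, sd in config.pause_regimes}
    for sample_id, tissue in samples:
        t5 = SignalTrack("five_prime")
        t3 = SignalTrack("three_prime")
        rows_chrom: list[np.ndarray] = []
        recs: list[tuple[str, str, np.ndarray, np.ndarray]] = []
        for et in truth:
            mean = et.activity[tissue] * sf[sample_id]
            strand_specs = []
            if et.directionality == "divergent":
                strand_specs.append(("+", et.plus_summit, et.shape_plus, mean / 2))
                strand_specs.append(("-", et.minus_summit, et.shape_minus, mean / 2))
            elif et.plus_summit is not None:
                strand_specs.append(("+", et.plus_summit, et.shape_plus, mean))
            else:
                strand_specs.append(("-", et.minus_summit, et.shape_minus, mean))
            sd = pause_sd.get(et.pause_mean, 5.0)
            for strand, summit, shape, m in strand_specs:
                n = int(_nb_draw(rng, m, config.nb_dispersion)[0])
                if n == 0:
                    continue
                p5 = _sample_5p_positions(rng, n, summit, et.interval, shape, config.peaked_decay)
                off = _pause_offsets(rng, n, et.pause_mean, sd)
                p3 = p5 + off if strand == "+" else p5 - off
                p3 = np.clip(p3, 0, config.chrom_length - 1)
                recs.append((et.interval.chrom, strand, p5, p3))
        # genome-wide uniform background, both strands
        if config.background_rate > 0:
            lam = config.background_rate * config.chrom_length / 1000.0
            for c in range(config.n_chroms):
                chrom = f"chr{c + 1}"
                for strand in ("+", "-"):
                    n = int(rng.poisson(lam))
                    if n == 0:
                        continue
                    p5 = rng.integers(0, config.chrom_length, size=n)
                    off = _pause_offsets(rng, n, 50.0, 10.0)
                    p3 = p5 + off if strand == "+" else p5 - off
                    p3 = np.clip(p3, 0, config.chrom_length - 1)
                    recs.append((chrom, strand, p5, p3))
        frames = []
        for chrom, strand, p5, p3 in recs:
            t5.add_positions(chrom, strand, p5)
            t3.add_positions(chrom, strand, p3)
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "strand": strand,
                     "five_prime_pos": p5, "three_prime_pos": p3}
                )
            )
        if frames:
            pair_df = pd.concat(frames, ignore_index=True)
        else:
            pair_df = pd.DataFrame(columns=list(ReadPairTable.COLUMNS))
        pairs[sample_id] = ReadPairTable(pair_df)
        tracks5[sample_id] = t5
        tracks3[sample_id] = t3

    return SimulatedDataset(
        config=config, genes=genes, truth=truth, elements=elements, design=design,
        size_factors=sf, tracks5=tracks5, tracks3=tracks3, pairs=pairs,
    )


def simulate_count_matrix(
    activity: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series | None,
    nb_dispersion: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw an elements x samples NB count matrix from an activity matrix.

    ``activity`` is elements x tissues (expected means); ``design`` maps
    sample_id to tissue.  A lighter-weight companion to
    :func:`simulate_dataset` for count-level studies (normalization,
    specificity, origin prediction) that do not need per-base geometry.
    """
    cols = {}
    for _, row in design.iterrows():
        mean = activity[row["tissue"]].to_numpy(dtype=float)
        if size_factors is not None:
            mean = mean * float(size_factors[row["sample_id"]])
        p = nb_dispersion / (nb_dispersion + np.maximum(mean, 1e-12))
        counts = rng.negative_binomial(nb_dispersion, p)
        counts[mean <= 0] = 0
        cols[row["sample_id"]] = counts
    return pd.DataFrame(cols, index=activity.index)


def degrade_library(
    track: SignalTrack,
    genes: GeneAnnotation,
    contamination_fraction: float,
    rng: np.random.Generator,
) -> SignalTrack:
    """Move a fraction of reads to uniform positions over gene bodies.

    Emulates poor 5' (cap) enrichment: run-on reads from gene bodies
    contaminate the library.  Relocated reads land on the sense strand of a
    gene chosen proportional to body length; total library size is
    conserved.  The QC stage's gene-body ratio should fail such libraries.
    """
    if not 0 <= contamination_fraction <= 1:
        raise ValueError("contamination_fraction must be in [0, 1]")
    out = track.copy()
    if contamination_fraction == 0:
        return out
    total = track.library_size
    n_move = int(round(contamination_fraction * total))
    if n_move == 0:
        return out
    # flatten reads to an indexable list of (chrom, strand, pos) with multiplicity,
    # then pick n_move reads uniformly without replacement from the multiset
    entries = []
    weights = []
    for chrom, strand in track.keys():
        pos, cnt = track.positions(chrom, strand)
        for p, c in zip(pos.tolist(), cnt.tolist()):
            entries.append((chrom, strand, p))
            weights.append(c)
    take_cnt = rng.multivariate_hypergeometric(np.asarray(weights, dtype=np.int64), n_move)
    gdf = genes.df
    body_len = (gdf["end"] - gdf["start"]).to_numpy(dtype=float)
    gene_p = body_len / body_len.sum()
    moved = 0
    for (chrom, strand, p), c in zip(entries, take_cnt.tolist()):
        if c <= 0:
            continue
        remaining = out._data[(chrom, strand)][p] - c
        if remaining == 0:
            del out._data[(chrom, strand)][p]
        else:
            out._data[(chrom, strand)][p] = remaining
        out._frozen.pop((chrom, strand), None)
        moved += c
    gi = rng.choice(len(gdf), size=moved, p=gene_p)
    for g in gi.tolist():
        row = gdf.iloc[g]
        pos = int(rng.integers(row["start"], row["end"]))
        out.add(row["chrom"], row["strand"], pos, 1)
    return out


@dataclass
class OriginStudy:
    """A count-level tissue-of-origin study with planted signatures."""

    activity: pd.DataFrame  # elements x tissues (expected means)
    train_design: pd.DataFrame  # sample_id, tissue
    train_counts: pd.DataFrame  # elements x training samples
    queries: pd.DataFrame  # sample_id, primary_site, metastatic_site
    query_counts: pd.DataFrame  # elements x query samples
    specific_elements: dict[str, list[str]]  # tissue -> planted signature ids


def simulate_origin_study(
    seed: int,
    n_tissues: int = 15,
    n_train: int = 93,
    n_queries: int = 23,
    n_specific_per_tissue: int = 30,
    n_shared: int = 150,
    baseline_mean: float = 100.0,
    fold_change: float = 8.0,
    off_level: float = 0.2,
    nb_dispersion: float = 50.0,
    primary_weight: float = 0.7,
) -> OriginStudy:
    """Simulate a normal-tissue training atlas plus metastatic-like queries.

    Mirrors the tissue-of-origin design: ``n_train`` normal samples over
    ``n_tissues`` tissue types (sizes as equal as possible), each tissue
    carrying a planted signature of ``n_specific_per_tissue`` elements ON
    in that tissue and near-silent elsewhere, over a shared background of
    ``n_shared`` ubiquitous elements.  Each query mixes its primary-site
    and metastatic-site signatures ``primary_weight : 1 − primary_weight``
    before NB sampling.  Lowering ``nb_dispersion`` raises count noise.
    """
    rng = np.random.default_rng(seed)
    tissues = [f"tissue{i:02d}" for i in range(n_tissues)]
    element_ids = [f"ub{i:04d}" for i in range(n_shared)]
    activity = {t: [baseline_mean] * n_shared for t in tissues}
    specific: dict[str, list[str]] = {t: [] for t in tissues}
    for t in tissues:
        for k in range(n_specific_per_tissue):
            eid = f"sp_{t}_{k:03d}"
            element_ids.append(eid)
            specific[t].append(eid)
            for u in tissues:
                activity[u].append(
                    baseline_mean * (fold_change if u == t else off_level)
                )
    act = pd.DataFrame(activity, index=element_ids)

    base, extra = divmod(n_train, n_tissues)
    rows = []
    for i, t in enumerate(tissues):
        for r in range(base + (1 if i < extra else 0)):
            rows.append((f"{t}_n{r}", t))
    train_design = pd.DataFrame(rows, columns=["sample_id", "tissue"])
    sf = pd.Series(
        np.exp(rng.uniform(np.log(0.5), np.log(2.0), len(train_design))),
        index=train_design["sample_id"],
    )
    train_counts = simulate_count_matrix(act, train_design, sf, nb_dispersion, rng)

    qrows = []
    qcols = {}
    for q in range(n_queries):
        primary = tissues[q % n_tissues]
        others = [t for t in tissues if t != primary]
        dest = others[int(rng.integers(len(others)))]
        sid = f"met{q:02d}"
        qrows.append((sid, primary, dest))
        mean = (
            primary_weight * act[primary] + (1 - primary_weight) * act[dest]
        ).to_numpy() * float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        p = nb_dispersion / (nb_dispersion + mean)
        qcols[sid] = rng.negative_binomial(nb_dispersion, p)
    queries = pd.DataFrame(qrows, columns=["sample_id", "primary_site", "metastatic_site"])
    query_counts = pd.DataFrame(qcols, index=act.index)
    return OriginStudy(
        activity=act,
        train_design=train_design,
        train_counts=train_counts,
        queries=queries,
        query_counts=query_counts,
        specific_elements=specific,
    )


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict:
    """Write the dataset as plain-text files; returns a manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    ds.design.to_csv(out / "design.tsv", sep="\t", index=False)
    files.append("design.tsv")
    ds.genes.to_tsv(out / "genes.tsv")
    files.append("genes.tsv")
    ds.truth_frame().to_csv(out / "elements_truth.tsv", sep="\t", index=False)
    files.append("elements_truth.tsv")
    with open(out / "elements_truth.bed", "w") as fh:
        for t in ds.truth:
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"{t.element_id}\t0\t.\n"
            )
    files.append("elements_truth.bed")
    for sample_id in ds.design["sample_id"]:
        for end, tracks in (("5p", ds.tracks5), ("3p", ds.tracks3)):
            for strand, tag in (("+", "plus"), ("-", "minus")):
                name = f"{sample_id}.{end}.{tag}.bedgraph"
                track = tracks[sample_id]
                # one file per (end, strand), all chroms concatenated
                with open(out / name, "w") as fh:
                    for chrom in track.chroms():
                        pos, cnt = track.positions(chrom, strand)
                        run = None
                        for p, c in zip(pos.tolist(), cnt.tolist()):
                            if run and p == run[1] + 1 and c == run[2]:
                                run = (run[0], p, c)
                                continue
                            if run:
                                fh.write(f"{chrom}\t{run[0]}\t{run[1] + 1}\t{run[2]}\n")
                            run = (p, p, c)
                        if run:
                            fh.write(f"{chrom}\t{run[0]}\t{run[1] + 1}\t{run[2]}\n")
                files.append(name)
        ds.pairs[sample_id].to_tsv(out / f"{sample_id}.pairs.tsv")
        files.append(f"{sample_id}.pairs.tsv")
    manifest = {
        "config": _config_json(ds.config),
        "n_samples": int(len(ds.design)),
        "n_elements": len(ds.truth),
        "files": files,
    }
    with open(out / "truth_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _config_json(cfg: TruthConfig) -> dict:
    d = asdict(cfg)
    d["tissues"] = dict(cfg.tissues)
    d["divergent_gap"] = list(cfg.divergent_gap)
    d["pause_regimes"] = [list(r) for r in cfg.pause_regimes]
    return d
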