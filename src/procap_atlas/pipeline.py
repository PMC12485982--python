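"""End-to-end pipeline: simulate → classify → QC → quantify → downstream.

One config object collects every analysis threshold (pairing gap 300 bp,
proximity ±500 bp, QC cutoff 0.025, SI cut −1.5, specificity cuts
0.1/0.02, top fraction 5%, PCA variance 90%) together with the synthetic
generator settings and a seed.  ``run_pipeline`` executes the stages in
dependency order, writes each stage's tables as TSV/BED/JSON next to a
manifest of outputs with SHA-256 checksums, and is byte-reproducible for
a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import elements as el
from . import qc as qc_mod
from . import shape as shape_mod
from .core_io import ReadPairTable
from .origin import hier_cluster, train_origin_model
from .pausing import classify_pausing, pause_distances
from .quantify import build_count_matrix, normalize, size_factors
from .specificity import TissueDesign, select_sets, specificity_scores, tissue_t_statistics
from .synthetic import TruthConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "classify", "qc", "quantify", "specificity", "shape",
              "pausing", "origin")


@dataclass
class PipelineConfig:
    """All pipeline thresholds (defaults are the published constants) plus
    the synthetic-data configuration and seed."""

    truth: TruthConfig = field(default_factory=TruthConfig)
    stages: tuple[str, ...] = ALL_STAGES
    pairing_gap: int = 300
    proximity_cutoff: int = 500
    qc_threshold: float = 0.025
    si_cutoff: float = -1.5
    min_reads_shape: int = 50
    distal_s_cut: float = 0.1
    proximal_s_cut: float = 0.02
    top_frac: float = 0.05
    pca_variance: float = 0.90
    peak_min_count: int = 20
    peak_window: int = 30
    min_reads_pause: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["truth"]["tissues"] = dict(self.truth.tissues)
        d["truth"]["divergent_gap"] = list(self.truth.divergent_gap)
        d["truth"]["pause_regimes"] = [list(r) for r in self.truth.pause_regimes]
        d["stages"] = list(self.stages)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        t = d.pop("truth", {})
        if "divergent_gap" in t:
            t["divergent_gap"] = tuple(t["divergent_gap"])
        if "pause_regimes" in t:
            t["pause_regimes"] = tuple(tuple(r) for r in t["pause_regimes"])
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(truth=TruthConfig(**t), **{k: v for k, v in d.items() if k != "truth"})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the enabled stages, writing outputs and a checksum manifest.

    Returns the manifest dict (also written as ``manifest.json``).  Stage
    outputs are write-once; rerunning with an identical config and seed
    reproduces identical checksums for all deterministic outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.json").write_text(config.to_json())
    manifest: dict = {"stages": [], "config": "resolved_config.json"}

    def record(stage: str, outputs: list[str], t0: float, **info) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "outputs": outputs,
                "checksums": {name: _sha256(out / name) for name in outputs},
                "wall_time_s": round(time.perf_counter() - t0, 4),
                **info,
            }
        )

    cfg = dataclasses.replace(config.truth, seed=config.seed)
    ds = simulate_dataset(cfg)
    design = TissueDesign.from_frame(ds.design)

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        sim_dir = out / "dataset"
        m = write_dataset(ds, sim_dir)
        record("simulate", [f"dataset/{f}" for f in m["files"]], t0,
               n_samples=m["n_samples"], n_elements=m["n_elements"])

    classified = None
    if "classify" in config.stages:
        t0 = time.perf_counter()
        pooled5 = shape_mod.pool_tissue_signal(list(ds.tracks5.values()))
        peaks = el.naive_peak_call(pooled5, config.peak_min_count, config.peak_window)
        plus = [p for p in peaks if p.interval.strand == "+"]
        minus = [p for p in peaks if p.interval.strand == "-"]
        classified = el.pair_divergent(plus, minus, config.pairing_gap)
        classified = el.annotate_proximity(classified, ds.genes, config.proximity_cutoff)
        classified = el.annotate_context(classified, ds.genes)
        rows = [
            {
                "element_id": e.element_id,
                "chrom": e.span.chrom,
                "start": e.span.start,
                "end": e.span.end,
                "directionality": e.directionality,
                "proximity": e.proximity,
                "context": e.context,
            }
            for e in classified
        ]
        pd.DataFrame(rows).to_csv(out / "elements.tsv", sep="\t", index=False)
        n_div = sum(e.directionality == "divergent" for e in classified)
        record("classify", ["elements.tsv"], t0,
               n_elements=len(classified), n_divergent=n_div)
        logger.info("classified %d elements (%d divergent)", len(classified), n_div)

    if "qc" in config.stages:
        t0 = time.perf_counter()
        reports = []
        for sid in ds.design["sample_id"]:
            expressed = qc_mod.select_expressed_genes(ds.tracks5[sid], ds.genes)
            rep = qc_mod.gene_body_ratio(
                ds.tracks5[sid], expressed, sample_id=sid, threshold=config.qc_threshold
            )
            reports.append(dataclasses.asdict(rep))
        pd.DataFrame(reports).to_csv(out / "qc.tsv", sep="\t", index=False)
        record("qc", ["qc.tsv"], t0,
               n_failed=sum(not r["passed"] for r in reports))

    norm = None
    counts = None
    if "quantify" in config.stages:
        if classified is None:
            raise RuntimeError("quantify requires the classify stage")
        t0 = time.perf_counter()
        counts = build_count_matrix(ds.tracks5, classified)
        s = size_factors(counts)
        norm = normalize(counts, s)
        counts.to_csv(out / "counts.tsv", sep="\t")
        s.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
        norm.log2.to_csv(out / "normalized_log2.tsv", sep="\t")
        record("quantify", ["counts.tsv", "size_factors.tsv", "normalized_log2.tsv"], t0)

    sets = None
    if "specificity" in config.stages:
        if norm is None:
            raise RuntimeError("specificity requires the quantify stage")
        t0 = time.perf_counter()
        res = specificity_scores(norm.scaled, design)
        scores_df = res.q.add_prefix("q_")
        scores_df["entropy"] = res.entropy
        scores_df["score"] = res.score
        scores_df.to_csv(out / "specificity.tsv", sep="\t")
        t_by_tissue = {
            t: tissue_t_statistics(norm.log2, design, t)
            for t in design.eligible_tissues()
        }
        outputs = ["specificity.tsv"]
        if len(t_by_tissue) >= 1:
            prox = pd.Series(
                {e.element_id: e.proximity for e in classified}, name="proximity"
            )
            sets = select_sets(
                t_by_tissue, res, prox,
                top_frac=config.top_frac,
                distal_cut=config.distal_s_cut,
                proximal_cut=config.proximal_s_cut,
            )
            rows = [
                {"set": tissue, "element_id": eid}
                for tissue in sorted(sets.specific)
                for eid in sets.specific[tissue]
            ] + [{"set": "non_specific", "element_id": eid} for eid in sets.non_specific]
            pd.DataFrame(rows).to_csv(out / "tissue_sets.tsv", sep="\t", index=False)
            outputs.append("tissue_sets.tsv")
        record("specificity", outputs, t0)

    if "shape" in config.stages:
        if classified is None:
            raise RuntimeError("shape requires the classify stage")
        t0 = time.perf_counter()
        rows = []
        n_filtered = 0
        for tissue in design.tissues:
            pooled = shape_mod.pool_tissue_signal(
                [ds.tracks5[s] for s in design.samples_of(tissue)]
            )
            scored, filtered = shape_mod.score_elements(
                pooled, classified, config.min_reads_shape
            )
            n_filtered += len(filtered)
            for sp, sm, cls in scored:
                for s in (sp, sm):
                    rows.append(
                        {
                            "tissue": tissue,
                            "element_id": s.element_id,
                            "strand": s.strand,
                            "n_reads": s.n_reads,
                            "n_positions": s.n_positions,
                            "si": s.si,
                            "label": s.label,
                            "category": cls.category,
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "shape.tsv", sep="\t", index=False)
        record("shape", ["shape.tsv"], t0, n_filtered=n_filtered)

    if "pausing" in config.stages:
        if classified is None:
            raise RuntimeError("pausing requires the classify stage")
        t0 = time.perf_counter()
        pooled_pairs = ReadPairTable(
            pd.concat([ds.pairs[s].df for s in ds.design["sample_id"]], ignore_index=True)
        )
        dists, tally = pause_distances(pooled_pairs, classified)
        labels = classify_pausing(dists, min_reads=config.min_reads_pause)
        rows = [
            {
                "element_id": eid,
                "n": d.n,
                "median": d.median,
                "pause_class": labels.get(eid, ""),
            }
            for eid, d in sorted(dists.items())
        ]
        pd.DataFrame(rows).to_csv(out / "pausing.tsv", sep="\t", index=False)
        record("pausing", ["pausing.tsv"], t0, **tally)

    if "origin" in config.stages:
        if norm is None:
            raise RuntimeError("origin requires the quantify stage")
        t0 = time.perf_counter()
        Z, order = hier_cluster(norm.log2)
        link = pd.DataFrame(Z, columns=["left", "right", "distance", "size"])
        link.to_csv(out / "linkage.tsv", sep="\t", index=False)
        pd.Series(order, name="sample_id").to_csv(out / "linkage_samples.tsv",
                                                  sep="\t", index=False)
        outputs = ["linkage.tsv", "linkage_samples.tsv"]
        if sets is not None and len(sets.specific) >= 2:
            model = train_origin_model(norm.log2, design, sets.specific)
            model.to_json(out / "origin_model.json")
            outputs.append("origin_model.json")
        record("origin", outputs, t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
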