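"""End-to-end orchestration: QC → split → detect → assemble → quantify →
select → tree → evaluate, with every stage re-runnable from its serialized
inputs.

A run writes all artifacts into a work directory:

    manifest_qc.tsv, qc_removals.tsv      sample QC
    split.json                            train/test ids + per-individual
                                          undersampled negatives
    kmer_tables/<sample>.tsv.gz           per-sample canonical k-mer counts
    specific_kmers/<individual>.tsv       detected specific k-mers
    candidates/<individual>.fasta         assembled candidate contigs
    abundance/candidates_train.rpkm.tsv   contig × train-sample RPKM
    fingerprints.fasta / fingerprints.tsv selected markers with thresholds
    tree.json                             the identification tree
    abundance/fingerprints_test.rpkm.tsv  test-sample RPKM
    evaluation/confusion.tsv, report.json held-out evaluation
    config.yaml                           the resolved configuration

Per-stage seeds are derived deterministically from the run seed and the stage
name, so running stages one at a time reproduces a full run bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import abundance as ab
from . import assembly as asm
from . import cohort as co
from . import identity as idt
from . import kmers as km
from . import selection as sel
from . import specificity as sp
from .seqcodes import ReadCodes, reads_to_codes

logger = logging.getLogger(__name__)

STAGES = ["qc", "split", "detect", "assemble", "quantify", "select", "tree", "evaluate"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults."""

    k: int = 31
    min_count: int = 3
    sparse_max_absent: float = 0.8
    ass_threshold: float = 0.8
    validation_ass_threshold: float = 0.8
    cv_folds: int = 6
    min_hits: int = 3
    asm_k: int | None = None           # assembly k; defaults to k
    asm_coverage_floor: int = 2
    min_contig_len: int = 100
    min_rpkm: float = 0.01
    roc_step: float = 0.001
    train_fraction: float = 0.7
    undersample_ratio: float = 2.0
    min_read_fraction_of_median: float = 0.1
    absolute_min_reads: int = 0
    excluded_sites: tuple[str, ...] = ()
    min_shared_kmers: int | None = None  # None = full-read containment mapping
    # per-individual θ1 overrides (the practical range is 0.8-0.9; noisier
    # individuals warrant the stricter value)
    ass_thresholds: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for theta in [self.ass_threshold, *self.ass_thresholds.values()]:
            if not 0.5 <= theta <= 1:
                raise ValueError(f"ass_threshold must be in [0.5, 1]; got {theta}")
        if not 0 < self.train_fraction <= 1:
            raise ValueError(f"train_fraction must be in (0, 1]; got {self.train_fraction}")
        if self.undersample_ratio <= 0:
            raise ValueError("undersample_ratio must be positive")
        for name in ("k", "min_count", "cv_folds", "min_hits", "min_contig_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.roc_step <= 0:
            raise ValueError("roc_step must be > 0")
        if not 0 <= self.sparse_max_absent <= 1:
            raise ValueError("sparse_max_absent must be in [0, 1]")

    @property
    def assembly_k(self) -> int:
        return self.asm_k if self.asm_k is not None else self.k

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["excluded_sites"] = list(self.excluded_sites)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "excluded_sites" in data:
            data["excluded_sites"] = tuple(data["excluded_sites"])
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return f"{zlib.crc32(payload.encode()):08x}"


def derive_seed(seed: int, name: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


class SampleCache:
    """In-process cache of per-sample window codes and k-mer count tables.

    Semantically transparent: every value is a pure function of the sample's
    FASTQ files and the configuration, so cached and staged runs agree.
    """

    def __init__(self, manifest: co.CohortManifest, config: PipelineConfig,
                 workdir: Path | None = None):
        self.manifest = manifest
        self.config = config
        self.workdir = workdir
        self._codes: dict[str, ReadCodes] = {}
        self._tables: dict[str, km.KmerCountTable] = {}

    def reads(self, sample_id: str) -> list[tuple[str, str]]:
        return co.load_sample_reads(self.manifest.get(sample_id))

    def read_codes(self, sample_id: str) -> ReadCodes:
        if sample_id not in self._codes:
            seqs = [s for _, s in self.reads(sample_id)]
            self._codes[sample_id] = reads_to_codes(seqs, self.config.k)
        return self._codes[sample_id]

    def table(self, sample_id: str) -> km.KmerCountTable:
        if sample_id in self._tables:
            return self._tables[sample_id]
        path = None
        if self.workdir is not None:
            path = self.workdir / "kmer_tables" / f"{sample_id}.tsv.gz"
            if path.exists():
                t = km.KmerCountTable.from_tsv(path)
                self._tables[sample_id] = t
                return t
        t = km.table_from_read_codes(
            self.read_codes(sample_id), self.config.min_count, sample_id
        )
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            t.to_tsv(path)
        self._tables[sample_id] = t
        return t


@dataclass
class PipelineResult:
    workdir: Path
    report: dict
    markers: list[sel.FingerprintMarker] = field(default_factory=list)
    tree: idt.TreeNode | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing upstream artifact {path}")
    return path


def _load_split(workdir: Path, stage: str) -> dict:
    return json.loads(_require(stage, workdir / "split.json").read_text())


def _qc_manifest(workdir: Path, stage: str) -> co.CohortManifest:
    return co.load_manifest(_require(stage, workdir / "manifest_qc.tsv"))


def run_stage(
    stage: str,
    config: PipelineConfig,
    workdir: str | Path,
    manifest_path: str | Path | None = None,
    cache: SampleCache | None = None,
) -> dict:
    """Run one pipeline stage from serialized inputs in ``workdir``.

    Returns a small dict of stage-level counts (also logged).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}")
    fn = globals()[f"_stage_{stage}"]
    try:
        info = fn(config, workdir, manifest_path, cache)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise StageError(stage, str(exc)) from exc
    logger.info("stage %s: %s", stage, info)
    return info


def _stage_qc(config, workdir: Path, manifest_path, cache) -> dict:
    if manifest_path is None:
        raise StageError("qc", "a manifest path is required")
    manifest = co.load_manifest(manifest_path)
    filtered, report = co.qc_filter(
        manifest,
        min_read_fraction_of_median=config.min_read_fraction_of_median,
        absolute_min_reads=config.absolute_min_reads,
        excluded_sites=config.excluded_sites,
    )
    filtered.to_tsv(workdir / "manifest_qc.tsv")
    report.to_csv(workdir / "qc_removals.tsv", sep="\t", index=False)
    return {"samples_retained": len(filtered), "samples_removed": len(report)}


def _stage_split(config, workdir: Path, manifest_path, cache) -> dict:
    manifest = _qc_manifest(workdir, "split")
    plan = co.split_cohort(
        manifest, config.train_fraction, derive_seed(config.seed, "split")
    )
    undersample = {}
    for ind in manifest.individuals():
        pos, neg = co.undersample_negatives(
            manifest, plan, ind, config.undersample_ratio,
            derive_seed(config.seed, f"undersample:{ind}"),
        )
        undersample[ind] = {"positives": pos, "negatives": neg}
    payload = {
        "train_ids": list(plan.train_ids),
        "test_ids": list(plan.test_ids),
        "seed": plan.seed,
        "undersample": undersample,
    }
    (workdir / "split.json").write_text(json.dumps(payload, indent=2))
    return {"n_train": len(plan.train_ids), "n_test": len(plan.test_ids)}


def _stage_detect(config, workdir: Path, manifest_path, cache) -> dict:
    manifest = _qc_manifest(workdir, "detect")
    split = _load_split(workdir, "detect")
    cache = cache or SampleCache(manifest, config, workdir)
    out = workdir / "specific_kmers"
    out.mkdir(exist_ok=True)
    counts = {}
    for ind in manifest.individuals():
        spec_cfg = sp.SpecificityConfig(
            ass_threshold=config.ass_thresholds.get(ind, config.ass_threshold),
            validation_ass_threshold=config.validation_ass_threshold,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        us = split["undersample"][ind]
        ids = us["positives"] + us["negatives"]
        labels = {s: (km.POSITIVE if s in set(us["positives"]) else km.NEGATIVE) for s in ids}
        matrix = km.build_matrix([cache.table(s) for s in ids], labels)
        matrix = km.filter_sparse(matrix, config.sparse_max_absent)
        records = sp.detect_specific_kmers(matrix, spec_cfg)
        sp.records_to_tsv(records, out / f"{ind}.tsv")
        counts[ind] = len(records)
    return {"specific_kmers": counts}


def _stage_assemble(config, workdir: Path, manifest_path, cache) -> dict:
    manifest = _qc_manifest(workdir, "assemble")
    split = _load_split(workdir, "assemble")
    cache = cache or SampleCache(manifest, config, workdir)
    out = workdir / "candidates"
    out.mkdir(exist_ok=True)
    counts = {}
    for ind in manifest.individuals():
        records = sp.records_from_tsv(
            _require("assemble", workdir / "specific_kmers" / f"{ind}.tsv")
        )
        kmers = [r.kmer for r in records if r.direction == sp.PRESENCE]
        if not kmers:
            raise StageError("assemble", f"no presence-direction k-mers for {ind}")
        recruited_reads: list[tuple[str, str]] = []
        for sid in split["undersample"][ind]["positives"]:
            reads = cache.reads(sid)
            rset = asm.recruit_reads(
                kmers, reads, config.min_hits, config.k, ind,
                read_codes=cache.read_codes(sid),
            )
            recruited_reads.extend(rset.reads)
        pooled = asm.RecruitedReadSet(ind, recruited_reads, {})
        contigs = asm.assemble_unitigs(
            pooled,
            k_asm=config.assembly_k,
            min_contig_len=config.min_contig_len,
            coverage_floor=config.asm_coverage_floor,
        )
        asm.contigs_to_fasta(contigs, out / f"{ind}.fasta")
        counts[ind] = {"recruited_reads": len(recruited_reads), "contigs": len(contigs)}
    return {"assembly": counts}


def _load_candidates(workdir: Path, manifest: co.CohortManifest, stage: str) -> list[asm.Contig]:
    contigs: list[asm.Contig] = []
    for ind in manifest.individuals():
        path = _require(stage, workdir / "candidates" / f"{ind}.fasta")
        contigs.extend(asm.load_contigs_fasta(path, ind))
    if not contigs:
        raise StageError(stage, "no candidate contigs assembled for any individual")
    return contigs


def _quantify(
    contigs: Sequence[asm.Contig],
    sample_ids: Sequence[str],
    cache: SampleCache,
    config: PipelineConfig,
) -> ab.AbundanceTable:
    index = ab.ContigIndex(contigs, config.k)
    results = [
        ab.map_reads(index, cache.read_codes(sid), config.min_shared_kmers,
                     config.k, sample_id=sid)
        for sid in sample_ids
    ]
    return ab.compute_rpkm(results)


def _stage_quantify(config, workdir: Path, manifest_path, cache) -> dict:
    manifest = _qc_manifest(workdir, "quantify")
    split = _load_split(workdir, "quantify")
    cache = cache or SampleCache(manifest, config, workdir)
    contigs = _load_candidates(workdir, manifest, "quantify")
    table = _quantify(contigs, split["train_ids"], cache, config)
    out = workdir / "abundance"
    out.mkdir(exist_ok=True)
    table.rpkm.to_csv(out / "candidates_train.rpkm.tsv", sep="\t", index_label="contig_id")
    table.counts.to_csv(out / "candidates_train.counts.tsv", sep="\t", index_label="contig_id")
    return {"contigs": len(contigs), "train_samples": len(split["train_ids"])}


def _load_abundance(workdir: Path, manifest: co.CohortManifest, split: dict, stage: str) -> ab.AbundanceTable:
    out = workdir / "abundance"
    rpkm = pd.read_csv(_require(stage, out / "candidates_train.rpkm.tsv"),
                       sep="\t", index_col="contig_id")
    counts = pd.read_csv(_require(stage, out / "candidates_train.counts.tsv"),
                         sep="\t", index_col="contig_id")
    contigs = _load_candidates(workdir, manifest, stage)
    lengths = pd.Series({c.contig_id: c.length for c in contigs})
    libs = pd.Series({s.sample_id: s.n_reads for s in manifest.samples
                      if s.sample_id in rpkm.columns})
    return ab.AbundanceTable(counts=counts, rpkm=rpkm, contig_lengths=lengths,
                             library_sizes=libs)


def _stage_select(config, workdir: Path, manifest_path, cache) -> dict:
    manifest = _qc_manifest(workdir, "select")
    split = _load_split(workdir, "select")
    table = _load_abundance(workdir, manifest, split, "select")
    contigs = _load_candidates(workdir, manifest, "select")
    markers = []
    for ind in manifest.individuals():
        own = [c for c in contigs if c.source_individual == ind]
        if not own:
            raise StageError("select", f"no candidate contigs for individual {ind}")
        us = split["undersample"][ind]
        sub = ab.AbundanceTable(
            counts=table.counts.loc[[c.contig_id for c in own]],
            rpkm=table.rpkm.loc[[c.contig_id for c in own]],
            contig_lengths=table.contig_lengths,
            library_sizes=table.library_sizes,
        )
        kept = sel.filter_contigs_by_abundance(sub, ind, us["positives"], config.min_rpkm)
        markers.append(
            sel.select_fingerprint(
                [c for c in own if c.contig_id in set(kept)],
                table,
                us["positives"],
                us["negatives"],
                ind,
                cv_folds=config.cv_folds,
                seed=derive_seed(config.seed, f"select:{ind}"),
                roc_step=config.roc_step,
            )
        )
    asm.contigs_to_fasta([m.contig for m in markers], workdir / "fingerprints.fasta")
    sel.markers_to_tsv(markers, workdir / "fingerprints.tsv")
    return {
        "fingerprints": {
            m.individual_id: {
                "contig_id": m.contig.contig_id,
                "length": m.contig.length,
                "rpkm_threshold": m.rpkm_threshold,
                "cv_auc_mean": m.cv_auc_mean,
            }
            for m in markers
        }
    }


def _load_markers(workdir: Path, stage: str) -> tuple[list[asm.Contig], pd.DataFrame]:
    contigs = asm.load_contigs_fasta(_require(stage, workdir / "fingerprints.fasta"))
    meta = pd.read_csv(_require(stage, workdir / "fingerprints.tsv"), sep="\t",
                       index_col="individual_id")
    return contigs, meta


def _fingerprint_rpkm(
    contigs: Sequence[asm.Contig],
    meta: pd.DataFrame,
    sample_ids: Sequence[str],
    cache: SampleCache,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Individuals × samples RPKM of the selected fingerprint contigs."""
    table = _quantify(contigs, sample_ids, cache, config)
    contig_of = meta["contig_id"].to_dict()
    rows = {ind: table.rpkm.loc[cid] for ind, cid in contig_of.items()}
    return pd.DataFrame(rows).T.loc[sorted(contig_of)]


def _stage_tree(config, workdir: Path, manifest_path, cache) -> dict:
    manifest = _qc_manifest(workdir, "tree")
    split = _load_split(workdir, "tree")
    cache = cache or SampleCache(manifest, config, workdir)
    contigs, meta = _load_markers(workdir, "tree")
    train_rpkm = _fingerprint_rpkm(contigs, meta, split["train_ids"], cache, config)
    (workdir / "abundance").mkdir(exist_ok=True)
    train_rpkm.to_csv(workdir / "abundance" / "fingerprints_train.rpkm.tsv",
                      sep="\t", index_label="individual_id")
    labels = {s: manifest.get(s).individual_id for s in split["train_ids"]}
    thresholds = meta["rpkm_threshold"].to_dict()
    tree = idt.build_tree(train_rpkm, thresholds, labels)
    idt.tree_to_json(tree, workdir / "tree.json")
    order = []
    node = tree
    while node.kind == idt.DECISION:
        order.append(node.individual_id)
        node = node.below
    return {"decision_order": order}


def _stage_evaluate(config, workdir: Path, manifest_path, cache) -> dict:
    manifest = _qc_manifest(workdir, "evaluate")
    split = _load_split(workdir, "evaluate")
    cache = cache or SampleCache(manifest, config, workdir)
    contigs, meta = _load_markers(workdir, "evaluate")
    tree = idt.tree_from_json(workdir / "tree.json")
    test_rpkm = _fingerprint_rpkm(contigs, meta, split["test_ids"], cache, config)
    (workdir / "abundance").mkdir(exist_ok=True)
    test_rpkm.to_csv(workdir / "abundance" / "fingerprints_test.rpkm.tsv",
                     sep="\t", index_label="individual_id")
    labels = {s: manifest.get(s).individual_id for s in split["test_ids"]}
    report = idt.evaluate_identifier(tree, test_rpkm, labels)
    out = workdir / "evaluation"
    out.mkdir(exist_ok=True)
    report.confusion.to_csv(out / "confusion.tsv", sep="\t", index_label="predicted")
    payload = {
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "predictions": report.predictions,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2))
    return {"accuracy": report.accuracy}


def run_pipeline(
    config: PipelineConfig,
    manifest_path: str | Path,
    workdir: str | Path,
) -> PipelineResult:
    """Run the full pipeline and return markers, tree and evaluation report."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    config.to_yaml(workdir / "config.yaml")
    logger.info("pipeline start: config hash %s", config.content_hash())
    report: dict = {"config_hash": config.content_hash()}
    cache: SampleCache | None = None
    for stage in STAGES:
        if cache is None and stage != "qc":
            cache = SampleCache(_qc_manifest(workdir, stage), config, workdir)
        report[stage] = run_stage(stage, config, workdir, manifest_path, cache)
    (workdir / "run_report.json").write_text(json.dumps(report, indent=2))
    contigs, meta = _load_markers(workdir, "evaluate")
    by_id = {c.contig_id: c for c in contigs}
    markers = [
        sel.FingerprintMarker(
            individual_id=ind,
            contig=by_id[row["contig_id"]],
            rpkm_threshold=float(row["rpkm_threshold"]),
            cv_auc_mean=float(row["cv_auc_mean"]),
            fold_thresholds=[],
            fold_aucs=[],
        )
        for ind, row in meta.iterrows()
    ]
    tree = idt.tree_from_json(workdir / "tree.json")
    return PipelineResult(workdir=workdir, report=report, markers=markers, tree=tree)


def identify_sample(
    fastq_paths: Sequence[str | Path],
    workdir: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[str, dict[str, float]]:
    """Classify an external sample against a finished run's fingerprints.

    Returns (label, per-fingerprint RPKM); the label is "unlabeled" for
    out-of-cohort donors.
    """
    workdir = Path(workdir)
    config = config or PipelineConfig.from_yaml(workdir / "config.yaml")
    contigs, meta = _load_markers(workdir, "evaluate")
    tree = idt.tree_from_json(_require("evaluate", workdir / "tree.json"))
    reads: list[str] = []
    for p in fastq_paths:
        reads.extend(seq for _, seq in co.read_fastq(p))
    index = ab.ContigIndex(contigs, config.k)
    result = ab.map_reads(index, reads, config.min_shared_kmers, config.k,
                          sample_id="query")
    table = ab.compute_rpkm([result])
    abund = {
        ind: float(table.rpkm.at[row["contig_id"], "query"])
        for ind, row in meta.iterrows()
    }
    return idt.identify(tree, abund), abund
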