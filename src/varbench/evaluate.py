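"""End-to-end evaluation: formats -> normalize -> stratify -> match ->
metrics -> association, driven by a single declarative run configuration.

The run writes plain TSV tables (``metrics.tsv`` mirroring the per-stratum
precision/recall layout, ``fp_variants.tsv``/``fn_variants.tsv`` pattern
matrices, one ``assoc_<label>.tsv`` per label) plus a ``manifest.json``
recording tool version, configuration echo and per-stage record counts, and
a human-readable ``summary.txt``.  Reruns on identical inputs are
byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .assoc import (DEFAULT_ALPHA, associate, build_pattern_matrix,
                    error_variants, write_pattern_tsv)
from .errors import ConfigError, ParseError, UnsupportedVariantError, VarbenchError
from .formats import (Callset, RegionSet, read_bed, read_depth_bedgraph,
                      read_fasta, read_vcf, depth_from_alignments)
from .match import match_callset
from .metrics import metrics_table, write_metrics_tsv
from .normalize import normalize_callset
from .stratify import StratumScheme, build_strata


@dataclass
class CallsetEntry:
    id: str
    path: str
    labels: Dict[str, str] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Paths and parameters of one evaluation run.

    ``depth`` points at a 4-column BED-graph of precomputed per-base depth;
    alternatively ``alignments`` names coordinate-sorted SAM text from which
    depth is computed with the scheme's MAPQ filter.  Relative paths resolve
    against ``base_dir``.
    """

    reference: str
    truth: str
    confident: str
    callsets: List[CallsetEntry]
    depth: Optional[str] = None
    alignments: Optional[str] = None
    target: Optional[str] = None
    strata: Optional[str] = None         # e.g. "0-9,10-30,>30"
    mapq_min: int = 60
    alpha: float = DEFAULT_ALPHA
    include_filtered: bool = False
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if not self.callsets:
            raise ConfigError("at least one callset is required")
        ids = [c.id for c in self.callsets]
        if len(set(ids)) != len(ids):
            raise ConfigError("callset ids must be unique")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if (self.depth is None) == (self.alignments is None):
            raise ConfigError("exactly one of depth/alignments is required")

    def resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        callsets = [CallsetEntry(id=e["id"], path=e["path"],
                                 labels=dict(e.get("labels") or {}))
                    for e in raw.get("callsets", [])]
        kwargs = {k: raw[k] for k in ("reference", "truth", "confident",
                                      "depth", "alignments", "target",
                                      "strata", "mapq_min", "alpha",
                                      "include_filtered") if k in raw}
        try:
            return cls(callsets=callsets, base_dir=path.parent, **kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


def run_evaluation(cfg: RunConfig, out_dir, log=None) -> Path:
    """Execute every pipeline stage and write the output tables.

    Any stage error aborts with the stage name and context attached.
    Returns the output directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"tool": "varbench", "version": __version__,
                      "stages": {}, "config": _echo_config(cfg)}

    def stage(name: str):
        if log:
            log(f"[{name}] ...")
        manifest["stages"][name] = {"started": time.strftime("%Y-%m-%dT%H:%M:%S")}
        return time.monotonic()

    def done(name: str, t0: float, **counts):
        manifest["stages"][name].update(counts)
        manifest["stages"][name]["seconds"] = round(time.monotonic() - t0, 3)
        if log:
            log(f"[{name}] done {counts}")

    try:
        t0 = stage("formats")
        reference = read_fasta(cfg.resolve(cfg.reference))
        lengths = {c: len(s) for c, s in reference.items()}
        truth_records = read_vcf(cfg.resolve(cfg.truth))
        confident = read_bed(cfg.resolve(cfg.confident))
        target = read_bed(cfg.resolve(cfg.target)) if cfg.target else None
        scheme = (StratumScheme.from_string(cfg.strata, cfg.mapq_min)
                  if cfg.strata else StratumScheme(mapq_min=cfg.mapq_min))
        if cfg.depth:
            depth = read_depth_bedgraph(cfg.resolve(cfg.depth))
        else:
            depth = depth_from_alignments(cfg.resolve(cfg.alignments),
                                          scheme.mapq_min)
        raw_callsets = {e.id: Callset(id=e.id,
                                      records=read_vcf(cfg.resolve(e.path)),
                                      labels=e.labels)
                        for e in cfg.callsets}
        done("formats", t0, truth_records=len(truth_records),
             callsets={k: len(v.records) for k, v in raw_callsets.items()})

        t0 = stage("normalize")
        truth = normalize_callset(
            Callset(id="truth", records=truth_records),
            reference, passing_only=not cfg.include_filtered)
        callsets = {k: normalize_callset(v, reference,
                                         passing_only=not cfg.include_filtered)
                    for k, v in raw_callsets.items()}
        done("normalize", t0, truth_atoms=len(truth.records),
             callset_atoms={k: len(v.records) for k, v in callsets.items()})

        t0 = stage("stratify")
        strata = build_strata(depth, scheme, confident, target, lengths)
        done("stratify", t0, **{n: strata[n].total_length()
                                for n in strata.names()})

        t0 = stage("match")
        match_results = {k: match_callset(v, truth, reference, strata)
                         for k, v in callsets.items()}
        done("match", t0)

        t0 = stage("metrics")
        table = metrics_table(match_results, strata.names())
        write_metrics_tsv(table, out_dir / "metrics.tsv")
        done("metrics", t0, rows=len(table))

        t0 = stage("assoc")
        labels = {k: v.labels for k, v in callsets.items()}
        assoc_df = pd.DataFrame()
        if len(callsets) >= 2:
            matrices = {}
            for kind, fname in (("FP", "fp_variants.tsv"),
                                ("FN", "fn_variants.tsv")):
                errs = {k: error_variants(match_results[k]["calling"], kind)
                        for k in callsets}
                matrices[kind] = build_pattern_matrix(errs, kind)
                write_pattern_tsv(matrices[kind], labels, out_dir / fname)
            assoc_df = associate(matrices, labels, cfg.alpha)
            for label_name in sorted({n for lab in labels.values() for n in lab}):
                sub = assoc_df[assoc_df["label"] == label_name] if not assoc_df.empty else assoc_df
                sub.to_csv(out_dir / f"assoc_{label_name}.tsv", sep="\t",
                           index=False)
        done("assoc", t0, tests=len(assoc_df))

        _write_summary(out_dir, table, assoc_df, strata)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except VarbenchError:
        raise
    except Exception as exc:  # attach the failing stage for diagnosis
        failing = next((n for n, s in reversed(list(manifest["stages"].items()))
                        if "seconds" not in s), "?")
        raise VarbenchError(f"stage {failing!r} failed: {exc}") from exc
    return out_dir


def _echo_config(cfg: RunConfig) -> Dict:
    return {
        "reference": cfg.reference, "truth": cfg.truth,
        "confident": cfg.confident, "target": cfg.target,
        "depth": cfg.depth, "alignments": cfg.alignments,
        "strata": cfg.strata, "mapq_min": cfg.mapq_min, "alpha": cfg.alpha,
        "include_filtered": cfg.include_filtered,
        "callsets": [{"id": e.id, "path": e.path, "labels": e.labels}
                     for e in cfg.callsets],
    }


def _write_summary(out_dir: Path, table: pd.DataFrame,
                   assoc_df: pd.DataFrame, strata) -> None:
    lines = [f"varbench {__version__} evaluation summary", ""]
    lines.append("stratum sizes (bp): " + ", ".join(
        f"{n}={strata[n].total_length()}" for n in strata.names()))
    lines.append("")
    header = ("callset", "stratum", "mode", "tp_query", "tp_truth", "fp",
              "fn", "precision", "recall", "f_star")
    lines.append("  ".join(f"{h:>10}" for h in header))
    for _, row in table.iterrows():
        cells = []
        for h in header:
            v = row[h]
            if isinstance(v, float):
                cells.append(f"{v:>10.4f}" if pd.notna(v) else f"{'.':>10}")
            elif v is None:
                cells.append(f"{'.':>10}")
            else:
                cells.append(f"{str(v):>10}")
        lines.append("  ".join(cells))
    lines.append("")
    if assoc_df is not None and len(assoc_df):
        n_sig = int(assoc_df["significant"].sum())
        lines.append(f"label-association tests: {len(assoc_df)}, "
                     f"significant after BY correction: {n_sig}")
    with open(out_dir / "summary.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# contributor pre-check
# ---------------------------------------------------------------------------

def precheck_callset(path, reference: Dict[str, str],
                     truth_path=None, confident: Optional[RegionSet] = None) -> Dict:
    """Local sanity diagnostics for a callset before submission.

    Reports parse validity, contig-name overlap with the reference (and the
    truth set when given), FILTER composition, how many records
    normalization changes, unsupported (symbolic) records, and the fraction
    of records inside the confident regions.
    """
    import pysam

    diagnostics: Dict = {"path": str(path), "parse_ok": True, "warnings": []}
    n = n_pass = n_symbolic = 0
    contigs = set()
    records = []
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.alts is None:
                    continue
                n += 1
                contigs.add(rec.contig)
                if list(rec.filter.keys()) in ([], ["PASS"]):
                    n_pass += 1
                if any(not set(a.upper()) <= set("ACGTN")
                       for a in rec.alts):
                    n_symbolic += 1
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: unreadable callset: {exc}") from exc
    diagnostics["records"] = n
    diagnostics["passing"] = n_pass
    diagnostics["unsupported_records"] = n_symbolic
    if n_symbolic:
        diagnostics["warnings"].append(
            f"{n_symbolic} records use symbolic/non-sequence alleles and "
            "will be rejected by normalization")
    ref_contigs = set(reference)
    overlap = contigs & ref_contigs
    diagnostics["contig_overlap"] = sorted(overlap)
    if contigs and not overlap:
        diagnostics["warnings"].append(
            f"no contig overlap with reference (callset: {sorted(contigs)[:3]}"
            f"..., reference: {sorted(ref_contigs)[:3]}...); check 'chr' prefixes")
    if truth_path is not None:
        truth_contigs = {r.contig for r in read_vcf(truth_path)}
        if contigs and not (contigs & truth_contigs):
            diagnostics["warnings"].append("no contig overlap with truth set")
    if overlap and not n_symbolic:
        try:
            records = read_vcf(path)
            cs = Callset(id="precheck", records=records)
            normalized = normalize_callset(cs, reference)
            raw_keys = {(r.contig, r.pos, r.ref, r.alts) for r in records}
            norm_keys = {(a.contig, a.pos, a.ref, (a.alt,))
                         for a in normalized.records}
            diagnostics["normalization_delta"] = len(norm_keys - raw_keys)
            if confident is not None and records:
                inside = sum(1 for r in records
                             if confident.contains(r.contig, r.pos0))
                diagnostics["fraction_in_confident"] = inside / len(records)
        except (UnsupportedVariantError, VarbenchError) as exc:
            diagnostics["warnings"].append(str(exc))
    return diagnostics
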