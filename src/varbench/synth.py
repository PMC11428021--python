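"""Synthetic benchmark fixtures with controlled error injection.

Generates everything an evaluation needs — reference FASTA, truth VCF,
confident regions, a per-base depth track, and label-annotated callsets —
so every pipeline stage is testable without any external dataset.  The
generator emulates the *shape* of a real exome benchmark (a diploid truth
set inside confident regions, piecewise-constant coverage spanning the
low/medium/high strata, callers that miss variants at depth-dependent
rates, call spurious variants, flip genotypes, merge neighbours into
complex replacements, and right-shift indels in repeats), not read-level
sequencing noise.

Error rates are configured per depth stratum and map directly onto the
expected metrics: recall = 1 - fn_rate and precision =
(1 - fn_rate) / (1 - fn_rate + fp_rate) per stratum in calling mode, and
the genotype-mismatch fraction equals gt_error_rate in expectation, because
false positives are drawn from confident in-stratum bases only and each
truth variant independently survives, errs or drops.

Randomness: every artifact (reference, truth, depth, each callset, planted
FPs) draws from its own stream sub-seeded from ``SimConfig.seed`` and a
stable name hash, so adding a callset never perturbs the others and
identical configs yield byte-identical fixture files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .formats import (HET, HOM, Callset, DepthTrack, RegionSet, VariantRecord,
                      write_bed, write_depth_bedgraph, write_fasta, write_vcf)
from .stratify import StratifiedRegions, StratumScheme, build_strata

_BASES = np.array(list("ACGT"))

DEFAULT_FN_RATE = {"low": 0.30, "medium": 0.10, "high": 0.05}
DEFAULT_FP_RATE = {"low": 0.15, "medium": 0.05, "high": 0.02}


@dataclass
class PlantedFPSet:
    """False positives shared verbatim by all callsets with a label value."""

    label: str
    value: str
    count: int = 10


@dataclass
class CallsetSim:
    """Per-callset simulation parameters; None falls back to config defaults."""

    id: str
    labels: Dict[str, str] = field(default_factory=dict)
    fn_rate: Optional[Dict[str, float]] = None
    fp_rate: Optional[Dict[str, float]] = None
    gt_error_rate: Optional[float] = None
    complex_merge_rate: Optional[float] = None
    right_shift_rate: Optional[float] = None


@dataclass
class SimConfig:
    """Study conditions for one synthetic benchmark fixture."""

    seed: int = 0
    reference_length: int = 100_000
    contig_count: int = 1
    truth_count: int = 500
    #: SNV / insertion / deletion / complex fractions (sum to 1)
    type_mix: Tuple[float, float, float, float] = (0.7, 0.1, 0.1, 0.1)
    het_fraction: float = 0.6
    min_spacing: int = 15
    #: depth drawn per stratum from these inclusive ranges, tiled in runs
    depth_ranges: Dict[str, Tuple[int, int]] = field(default_factory=lambda: {
        "low": (0, 9), "medium": (10, 30), "high": (31, 60)})
    depth_run_length: int = 300
    confident_coverage: float = 0.97
    fn_rate: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FN_RATE))
    fp_rate: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FP_RATE))
    gt_error_rate: float = 0.05
    complex_merge_rate: float = 0.10
    right_shift_rate: float = 0.30
    callsets: List[CallsetSim] = field(default_factory=list)
    planted: List[PlantedFPSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix fractions must sum to 1")
        for rates in (self.fn_rate, self.fp_rate):
            for v in rates.values():
                if not 0 <= v <= 1:
                    raise ValueError("rates must lie in [0, 1]")
        for v in (self.gt_error_rate, self.complex_merge_rate,
                  self.right_shift_rate, self.het_fraction):
            if not 0 <= v <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def rng(self, artifact: str) -> np.random.Generator:
        """Independent stream per artifact, derived from seed and name."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF,
                                    zlib.crc32(artifact.encode())]))


def _contig_names(cfg: SimConfig) -> List[str]:
    return [f"chr{i + 1}" for i in range(cfg.contig_count)]


def generate_reference(cfg: SimConfig) -> Dict[str, str]:
    """Uniform-random A/C/G/T reference, reproducible from the seed."""
    if cfg.reference_length < 1000:
        raise ValueError("reference_length must be >= 1000")
    rng = cfg.rng("reference")
    out = {}
    for name in _contig_names(cfg):
        out[name] = "".join(_BASES[rng.integers(0, 4, cfg.reference_length)])
    return out


def _random_seq(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def generate_truth(cfg: SimConfig,
                   reference: Mapping[str, str]) -> Tuple[List[VariantRecord], RegionSet]:
    """Truth records (requested count and type mix) plus confident regions.

    Variants are spaced >= ``min_spacing`` apart.  Confident regions cover
    ~``confident_coverage`` of the reference, with gaps placed so that some
    variants fall outside them (exercising confident-region filtering).
    """
    rng = cfg.rng("truth")
    contigs = _contig_names(cfg)
    # feasibility: positions per contig on a spacing grid
    slots = [(c, p) for c in contigs
             for p in range(10, len(reference[c]) - 10, cfg.min_spacing)]
    if cfg.truth_count > len(slots):
        raise ValueError(
            f"cannot place {cfg.truth_count} variants with spacing "
            f"{cfg.min_spacing} on {sum(map(len, reference.values()))} bp")
    chosen = sorted(rng.choice(len(slots), size=cfg.truth_count, replace=False))
    records: List[VariantRecord] = []
    kinds = rng.choice(4, size=cfg.truth_count, p=list(cfg.type_mix))
    for i, (slot, kind) in enumerate(zip(chosen, kinds)):
        contig, pos = slots[slot]  # pos is 1-based here (grid starts at 10)
        seq = reference[contig]
        zyg = HET if rng.random() < cfg.het_fraction else HOM
        gt = (0, 1) if zyg == HET else (1, 1)
        if kind == 0:  # SNV
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        elif kind == 1:  # insertion
            ref = seq[pos - 1]
            alt = ref + _random_seq(rng, int(rng.integers(1, 4)))
        elif kind == 2:  # deletion
            d = int(rng.integers(1, 4))
            ref = seq[pos - 1:pos + d]
            alt = seq[pos - 1]
        else:  # complex replacement, anchored, not trimmable
            k = int(rng.integers(3, 6))
            ref = seq[pos - 1:pos - 1 + k]
            while True:
                alt = ref[0] + _random_seq(rng, int(rng.integers(1, 5)))
                if alt != ref and alt[-1] != ref[-1]:
                    break
        records.append(VariantRecord(
            contig=contig, pos=pos, ref=ref, alts=(alt,), genotype=gt,
            source_id=f"truth:{i}"))
    records.sort(key=lambda r: (r.contig, r.pos))
    # confident regions: whole contigs minus random gaps
    gaps_frac = 1.0 - cfg.confident_coverage
    regions: List[Tuple[str, int, int]] = []
    for contig in contigs:
        length = len(reference[contig])
        gap_total = int(length * gaps_frac)
        n_gaps = max(1, gap_total // 400)
        gap_starts = sorted(rng.integers(0, length - 500, size=n_gaps))
        cursor = 0
        for gs in gap_starts:
            ge = gs + max(50, gap_total // n_gaps)
            if gs <= cursor:
                cursor = max(cursor, ge)
                continue
            regions.append((contig, cursor, gs))
            cursor = ge
        if cursor < length:
            regions.append((contig, cursor, length))
    return records, RegionSet(regions)


def generate_depth_track(cfg: SimConfig,
                         reference: Mapping[str, str]) -> DepthTrack:
    """Piecewise-constant depth tiling every contig through all strata."""
    rng = cfg.rng("depth")
    names = list(cfg.depth_ranges)
    runs: List[Tuple[str, int, int, int]] = []
    for contig in _contig_names(cfg):
        length = len(reference[contig])
        cursor = 0
        i = 0
        while cursor < length:
            stratum = names[i % len(names)]
            lo, hi = cfg.depth_ranges[stratum]
            d = int(rng.integers(lo, hi + 1))
            end = min(length, cursor + cfg.depth_run_length)
            runs.append((contig, cursor, end, d))
            cursor = end
            i += 1
    return DepthTrack(runs)


# ---------------------------------------------------------------------------
# callset generation
# ---------------------------------------------------------------------------

def _flip_genotype(record: VariantRecord) -> VariantRecord:
    if record.zygosity == HET:
        return record.with_(genotype=(1, 1), zygosity=HOM)
    return record.with_(genotype=(0, 1), zygosity=HET)


def _right_shift(record: VariantRecord, seq: str, max_pos: int) -> VariantRecord:
    """Re-express an anchored indel at its right-most equivalent position."""
    pos, ref, alt = record.pos, record.ref, record.alts[0]
    if len(ref) == len(alt) or ref[0] != alt[0]:
        return record
    if len(ref) > len(alt):  # deletion of segment ref[1:]
        i, j = pos, pos + len(ref) - 2  # 0-based segment [i, j]
        while j + 1 < len(seq) and j + 1 <= max_pos and seq[i] == seq[j + 1]:
            i += 1
            j += 1
        new_pos = i  # anchor base index 0-based = i-1 -> 1-based i
        ref2 = seq[new_pos - 1:j + 1]
        return record.with_(pos=new_pos, ref=ref2, alts=(ref2[0],))
    # insertion of segment alt[1:] after anchor pos
    ins = alt[1:]
    anchor0 = pos - 1  # 0-based anchor
    while anchor0 + 1 < len(seq) and anchor0 + 1 <= max_pos and ins[0] == seq[anchor0 + 1]:
        anchor0 += 1
        ins = ins[1:] + ins[0]
    new_pos = anchor0 + 1
    return record.with_(pos=new_pos, ref=seq[anchor0], alts=(seq[anchor0] + ins,))


def _merge_pair(a: VariantRecord, b: VariantRecord, seq: str) -> Optional[VariantRecord]:
    """Merge two nearby same-genotype records into one complex replacement."""
    if a.contig != b.contig or a.zygosity != b.zygosity:
        return None
    start0 = a.pos0
    end0 = b.pos0 + len(b.ref)
    if end0 - start0 > 20 or b.pos0 < a.pos0 + len(a.ref):
        return None
    segment = seq[start0:end0]
    merged = (a.alts[0]
              + seq[a.pos0 + len(a.ref):b.pos0]
              + b.alts[0])
    if merged == segment or len(segment) < 2 or len(merged) < 2:
        return None
    return VariantRecord(contig=a.contig, pos=a.pos, ref=segment,
                         alts=(merged,), genotype=a.genotype,
                         zygosity=a.zygosity,
                         source_id=f"{a.source_id}+{b.source_id}")


def _generate_planted(cfg: SimConfig, reference: Mapping[str, str],
                      confident: RegionSet,
                      truth_pos: set) -> Dict[Tuple[str, str], List[VariantRecord]]:
    """Planted FP records per (label, value), identical across callsets."""
    out: Dict[Tuple[str, str], List[VariantRecord]] = {}
    for spec in cfg.planted:
        rng = cfg.rng(f"planted:{spec.label}={spec.value}")
        records: List[VariantRecord] = []
        used = set(truth_pos)
        attempts = 0
        while len(records) < spec.count and attempts < 10000:
            attempts += 1
            region = list(confident)[int(rng.integers(0, len(confident)))]
            pos0 = int(rng.integers(region.start, region.end))
            key = (region.contig, pos0)
            if key in used or any((region.contig, pos0 + d) in used
                                  for d in range(-8, 9)):
                continue
            used.add(key)
            seq = reference[region.contig]
            ref = seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            records.append(VariantRecord(
                contig=region.contig, pos=pos0 + 1, ref=ref, alts=(alt,),
                genotype=(0, 1), source_id=f"planted:{spec.label}={spec.value}"))
        out[(spec.label, spec.value)] = records
    return out


def generate_callset(cfg: SimConfig, spec: CallsetSim,
                     truth: Sequence[VariantRecord],
                     reference: Mapping[str, str],
                     strata: StratifiedRegions,
                     planted: Optional[Mapping[Tuple[str, str],
                                               List[VariantRecord]]] = None) -> Callset:
    """One callset derived from the truth with controlled error injection.

    Per stratum, truth records are dropped at ``fn_rate`` and spurious SNVs
    added at ``fp_rate`` (drawn uniformly from confident in-stratum bases
    not occupied by truth variants).  Kept records have their genotype
    flipped het<->hom at ``gt_error_rate``, adjacent same-genotype pairs
    merged into complex replacements at ``complex_merge_rate``, and indels
    re-expressed right-shifted at ``right_shift_rate``.  Planted
    label-associated FPs are appended verbatim for matching labels.
    """
    rng = cfg.rng(f"callset:{spec.id}")
    fn_rate = spec.fn_rate or cfg.fn_rate
    fp_rate = spec.fp_rate or cfg.fp_rate
    gt_err = cfg.gt_error_rate if spec.gt_error_rate is None else spec.gt_error_rate
    merge_rate = (cfg.complex_merge_rate if spec.complex_merge_rate is None
                  else spec.complex_merge_rate)
    shift_rate = (cfg.right_shift_rate if spec.right_shift_rate is None
                  else spec.right_shift_rate)

    stratum_of = {t.source_id: strata.assign(t.contig, t.pos0) for t in truth}
    kept: List[VariantRecord] = []
    n_in_stratum: Dict[str, int] = {n: 0 for n in strata.names()}
    for t in truth:
        s = stratum_of[t.source_id]
        if s is None:
            kept.append(t)  # outside evaluation scope; carried through
            continue
        n_in_stratum[s] += 1
        if rng.random() < fn_rate.get(s, 0.0):
            continue
        rec = t
        if rng.random() < gt_err:
            rec = _flip_genotype(rec)
        kept.append(rec)

    # complex merges of adjacent kept pairs
    merged: List[VariantRecord] = []
    i = 0
    while i < len(kept):
        a = kept[i]
        if (merge_rate > 0 and i + 1 < len(kept)
                and rng.random() < merge_rate):
            m = _merge_pair(a, kept[i + 1], reference[a.contig])
            if m is not None:
                merged.append(m)
                i += 2
                continue
        merged.append(a)
        i += 1

    # right-shift indel representations (bounded by the next record)
    shifted: List[VariantRecord] = []
    for j, rec in enumerate(merged):
        is_indel = (len(rec.ref) != len(rec.alts[0])
                    and rec.ref[0] == rec.alts[0][0]
                    and min(len(rec.ref), len(rec.alts[0])) == 1)
        if is_indel and rng.random() < shift_rate:
            nxt = merged[j + 1] if j + 1 < len(merged) and merged[j + 1].contig == rec.contig else None
            max_pos = (nxt.pos0 - 2) if nxt is not None else len(reference[rec.contig]) - 2
            rec = _right_shift(rec, reference[rec.contig], max_pos)
        shifted.append(rec)

    # spurious calls per stratum
    truth_pos = {(t.contig, t.pos0 + d) for t in truth
                 for d in range(-cfg.min_spacing // 2, cfg.min_spacing // 2 + 1)}
    fps: List[VariantRecord] = []
    for s in strata.names():
        rate = fp_rate.get(s, 0.0)
        if rate <= 0 or n_in_stratum[s] == 0:
            continue
        n_fp = int(rng.binomial(n_in_stratum[s], rate))
        regions = list(strata[s])
        if not regions:
            continue
        weights = np.array([r.end - r.start for r in regions], dtype=float)
        weights /= weights.sum()
        used = set()
        placed = 0
        attempts = 0
        while placed < n_fp and attempts < 50 * n_fp + 100:
            attempts += 1
            region = regions[int(rng.choice(len(regions), p=weights))]
            pos0 = int(rng.integers(region.start, region.end))
            key = (region.contig, pos0)
            if key in truth_pos or key in used:
                continue
            used.add(key)
            seq = reference[region.contig]
            ref = seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            zyg = HET if rng.random() < cfg.het_fraction else HOM
            fps.append(VariantRecord(
                contig=region.contig, pos=pos0 + 1, ref=ref, alts=(alt,),
                genotype=(0, 1) if zyg == HET else (1, 1),
                source_id=f"{spec.id}:fp:{placed}"))
            placed += 1

    records = shifted + fps
    if planted:
        for (label, value), recs in planted.items():
            if spec.labels.get(label) == value:
                records.extend(recs)
    return Callset(id=spec.id, records=records, labels=dict(spec.labels))


# ---------------------------------------------------------------------------
# fixture directory
# ---------------------------------------------------------------------------

def generate_fixture(cfg: SimConfig, out_dir,
                     scheme: Optional[StratumScheme] = None) -> Path:
    """Write a complete, immediately evaluable fixture directory.

    Contents: ``reference.fa``, ``truth.vcf``, ``confident.bed``,
    ``depth.bedgraph``, ``callsets/<id>.vcf``, ``labels.tsv`` and a
    ``config.yaml`` that the ``evaluate`` command consumes directly.
    """
    scheme = scheme or StratumScheme()
    out_dir = Path(out_dir)
    (out_dir / "callsets").mkdir(parents=True, exist_ok=True)
    reference = generate_reference(cfg)
    truth, confident = generate_truth(cfg, reference)
    depth = generate_depth_track(cfg, reference)
    lengths = {c: len(s) for c, s in reference.items()}
    strata = build_strata(depth, scheme, confident, contig_lengths=lengths)
    planted = _generate_planted(cfg, reference, confident,
                                {(t.contig, t.pos0) for t in truth})
    write_fasta(reference, out_dir / "reference.fa")
    write_vcf(truth, out_dir / "truth.vcf", lengths)
    write_bed(confident, out_dir / "confident.bed")
    write_depth_bedgraph(depth, out_dir / "depth.bedgraph")
    entries = []
    with open(out_dir / "labels.tsv", "w") as fh:
        fh.write("callset\tlabel\tvalue\n")
        for spec in cfg.callsets:
            cs = generate_callset(cfg, spec, truth, reference, strata, planted)
            write_vcf(cs.records, out_dir / "callsets" / f"{spec.id}.vcf", lengths)
            for name, value in sorted(spec.labels.items()):
                fh.write(f"{spec.id}\t{name}\t{value}\n")
            entries.append({"id": spec.id,
                            "path": f"callsets/{spec.id}.vcf",
                            "labels": dict(spec.labels)})
    run_cfg = {
        "reference": "reference.fa",
        "truth": "truth.vcf",
        "confident": "confident.bed",
        "depth": "depth.bedgraph",
        "callsets": entries,
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)
    return out_dir
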