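"""Core genomic data types and readers/writers for the standard file formats.

Coordinate conventions are handled strictly: :class:`VariantRecord` positions
are 1-based (VCF convention) while all region and depth arithmetic is 0-based
half-open (BED convention).  The conversion happens exactly once, at
variant-to-region queries (:meth:`VariantRecord.pos0`).

VCF and SAM text are parsed with pysam/htslib; FASTA with Biopython.  The
interval containers (:class:`RegionSet`, :class:`DepthTrack`) are maximally
merged, sorted, half-open structures — the currency of the stratification and
matching stages.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import pysam
from Bio import SeqIO

from .errors import ParseError, UnsupportedVariantError

_ALLELE_RE = re.compile(r"^[ACGTN]+$")

#: zygosity classes used throughout the comparator
HET = "het"
HOM = "hom"
HALF = "half"  # allele present once, partner allele unknown / other-alt


def _classify_genotype(genotype: Optional[Tuple[Optional[int], ...]],
                       alt_index: int = 1) -> Optional[str]:
    """Map a genotype tuple onto het/hom/half for a given alt index."""
    if genotype is None:
        return None
    count = sum(1 for a in genotype if a == alt_index)
    if count == 0:
        return None
    if count >= 2:
        return HOM
    others = [a for a in genotype if a != alt_index]
    if any(a is None for a in others) or any(a not in (0, None) for a in others):
        return HALF
    return HET


@dataclass(frozen=True)
class VariantRecord:
    """One VCF-style small-variant record.

    ``pos`` is the 1-based position of the first REF base.  ``genotype`` is
    the unordered allele-index tuple from the first sample's GT (``None`` when
    the record carries no genotype; individual entries may be ``None`` for
    half-missing calls such as ``1/.``).  ``zygosity`` caches the het/hom/half
    class; it is set explicitly by multiallelic projection and derived from
    the genotype otherwise.
    """

    contig: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    genotype: Optional[Tuple[Optional[int], ...]] = None
    phased: bool = False
    passing: bool = True
    filter_text: str = "PASS"
    source_id: str = ""
    zygosity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.contig}:{self.pos}: pos must be >= 1")
        if not self.alts:
            raise ValueError(f"{self.contig}:{self.pos}: at least one alt required")
        for allele in (self.ref, *self.alts):
            if not _ALLELE_RE.match(allele):
                raise UnsupportedVariantError(
                    f"{self.contig}:{self.pos}: unsupported allele {allele!r} "
                    "(only A/C/G/T/N sequence alleles are evaluated)")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"{self.contig}:{self.pos}: ref == alt ({alt})")
        if self.genotype is not None:
            for a in self.genotype:
                if a is not None and not (0 <= a <= len(self.alts)):
                    raise ValueError(
                        f"{self.contig}:{self.pos}: genotype index {a} out of range")
        if self.zygosity is None and self.genotype is not None and len(self.alts) == 1:
            object.__setattr__(self, "zygosity", _classify_genotype(self.genotype))

    @property
    def pos0(self) -> int:
        """0-based position of the first REF base."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the REF span."""
        return self.pos - 1 + len(self.ref)

    def with_(self, **kw) -> "VariantRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class Region:
    """Half-open genomic interval, 0-based."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.contig}:{self.start}-{self.end}")


class RegionSet:
    """Sorted, pairwise-disjoint, maximally merged half-open intervals per contig.

    Overlapping or adjacent input intervals are merged on construction, so two
    RegionSets covering the same bases always compare equal.
    """

    def __init__(self, regions: Iterable[Tuple[str, int, int]] = ()) -> None:
        raw: Dict[str, List[Tuple[int, int]]] = {}
        for contig, start, end in regions:
            if not (0 <= start < end):
                raise ValueError(f"invalid region {contig}:{start}-{end}")
            raw.setdefault(contig, []).append((start, end))
        self._regions: Dict[str, List[Tuple[int, int]]] = {}
        for contig, ivs in raw.items():
            ivs.sort()
            merged: List[Tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:  # overlap or adjacency
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._regions[contig] = merged
        # starts cache for point queries
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self._regions.items()}

    def contigs(self) -> List[str]:
        return sorted(self._regions)

    def regions(self, contig: str) -> List[Tuple[int, int]]:
        return list(self._regions.get(contig, []))

    def __iter__(self) -> Iterator[Region]:
        for contig in self.contigs():
            for s, e in self._regions[contig]:
                yield Region(contig, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._regions.values())

    def __bool__(self) -> bool:
        return any(self._regions.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self._regions == other._regions

    def __repr__(self) -> str:
        return f"RegionSet({sum(e - s for c in self._regions for s, e in self._regions[c])} bp, {len(self)} regions)"

    def total_length(self) -> int:
        return sum(e - s for ivs in self._regions.values() for s, e in ivs)

    def contains(self, contig: str, pos0: int) -> bool:
        """Membership of a single 0-based position."""
        starts = self._starts.get(contig)
        if not starts:
            return False
        i = bisect_right(starts, pos0) - 1
        if i < 0:
            return False
        return pos0 < self._regions[contig][i][1]

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Exact interval intersection (commutative, result subset of both)."""
        out: List[Tuple[str, int, int]] = []
        for contig in self._regions:
            a = self._regions[contig]
            b = other._regions.get(contig)
            if not b:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    out.append((contig, s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out)

    def union(self, other: "RegionSet") -> "RegionSet":
        items = [(r.contig, r.start, r.end) for r in self]
        items += [(r.contig, r.start, r.end) for r in other]
        return RegionSet(items)


class DepthTrack:
    """Run-length encoded per-base read depth.

    Runs are sorted, disjoint, half-open ``(start, end, depth)`` triples per
    contig with integer depth >= 0; consecutive equal-depth runs are merged.
    Bases not covered by any run have implicit depth 0.
    """

    def __init__(self, runs: Iterable[Tuple[str, int, int, int]] = ()) -> None:
        raw: Dict[str, List[Tuple[int, int, int]]] = {}
        for contig, start, end, depth in runs:
            if not (0 <= start < end):
                raise ValueError(f"invalid depth run {contig}:{start}-{end}")
            if depth < 0:
                raise ValueError(f"negative depth {depth} at {contig}:{start}-{end}")
            raw.setdefault(contig, []).append((start, end, int(depth)))
        self._runs: Dict[str, List[Tuple[int, int, int]]] = {}
        for contig, rr in raw.items():
            rr.sort()
            merged: List[Tuple[int, int, int]] = []
            for s, e, d in rr:
                if merged and s < merged[-1][1]:
                    raise ValueError(
                        f"overlapping depth runs at {contig}:{s} (previous run ends "
                        f"at {merged[-1][1]})")
                if merged and s == merged[-1][1] and d == merged[-1][2]:
                    merged[-1] = (merged[-1][0], e, d)
                else:
                    merged.append((s, e, d))
            self._runs[contig] = merged

    def contigs(self) -> List[str]:
        return sorted(self._runs)

    def runs(self, contig: str) -> List[Tuple[int, int, int]]:
        return list(self._runs.get(contig, []))

    def __iter__(self) -> Iterator[Tuple[str, int, int, int]]:
        for contig in self.contigs():
            for s, e, d in self._runs[contig]:
                yield contig, s, e, d

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        return self._runs == other._runs

    def __repr__(self) -> str:
        return f"DepthTrack({sum(len(v) for v in self._runs.values())} runs)"


@dataclass
class Callset:
    """A named, label-annotated collection of variant records.

    ``labels`` maps label names (e.g. ``caller``, ``mapper``) to categorical
    values; any property of the producing pipeline can be annotated this way.
    Records are kept sorted by (contig, pos).
    """

    id: str
    records: List = field(default_factory=list)
    labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.contig, r.pos))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf(path, passing_only: bool = False) -> List[VariantRecord]:
    """Read a (plain or bgzip) VCF into :class:`VariantRecord` objects.

    Records are returned in file order; multi-allelic records are preserved
    as-is.  The genotype is taken from the first sample's GT; a missing GT
    flags the record genotype-missing rather than erroring.  ALT="." lines
    (explicit non-variants) are skipped.  Symbolic alleles raise
    :class:`UnsupportedVariantError`.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    n_header = str(vf.header).count("\n")
    out: List[VariantRecord] = []
    idx = 0
    try:
        for idx, rec in enumerate(vf, start=1):
            if rec.alts is None:
                continue  # non-variant line
            genotype: Optional[Tuple[Optional[int], ...]] = None
            phased = False
            if rec.samples:
                sample = rec.samples[0]
                try:
                    gt = sample["GT"]
                except KeyError:
                    gt = None
                if gt is not None and any(a is not None for a in gt):
                    genotype = tuple(gt)
                    phased = bool(sample.phased)
            filters = list(rec.filter.keys())
            passing = filters in ([], ["PASS"])
            record = VariantRecord(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref.upper(),
                alts=tuple(a.upper() for a in rec.alts),
                genotype=genotype,
                phased=phased,
                passing=passing,
                filter_text=";".join(filters) if filters else ".",
                source_id=f"{Path(path).name}:{idx}",
            )
            if passing or not passing_only:
                out.append(record)
    except UnsupportedVariantError:
        raise
    except (ValueError, OSError) as exc:
        raise ParseError(
            f"{path}: malformed VCF record near line {n_header + idx + 1}: {exc}"
        ) from exc
    finally:
        vf.close()
    return out


def read_bed(path) -> RegionSet:
    """Read a 3+ column BED (0-based half-open) into a merged RegionSet."""
    regions: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {fields[0]}:{start}-{end}")
            regions.append((fields[0], start, end))
    return RegionSet(regions)


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into a contig -> uppercase sequence mapping.

    The contig name is the token before the first whitespace.  Duplicate
    contig names are an error.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate contig name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_depth_bedgraph(path) -> DepthTrack:
    """Read a 4-column BED-graph of integer per-base depth."""
    runs: List[Tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 BED-graph columns")
            try:
                start, end, depth = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            if depth < 0:
                raise ParseError(f"{path}:{lineno}: negative depth {depth}")
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid interval")
            runs.append((fields[0], start, end, depth))
    try:
        return DepthTrack(runs)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# reference-consuming CIGAR ops; M/=/X/D count toward depth, N does not
_REF_OPS = {0: True, 2: True, 3: False, 7: True, 8: True}


def depth_from_alignments(sam_path, mapq_min: int = 60) -> DepthTrack:
    """Per-base depth from coordinate-sorted SAM text with a MAPQ filter.

    A base is covered by a read when a reference-consuming CIGAR operation
    (M/=/X/D) of that read spans it and the read's MAPQ is >= ``mapq_min``.
    Unmapped, secondary and supplementary alignments are excluded.  N (intron
    skip) advances along the reference without contributing depth.
    """
    sam_path = str(sam_path)
    events: Dict[str, Dict[int, int]] = {}
    last: Dict[str, int] = {}
    seen: List[str] = []
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            contig = read.reference_name
            if seen and contig != seen[-1]:
                if contig in seen:
                    raise ParseError(
                        f"{sam_path}: input not coordinate-sorted "
                        f"(contig {contig} seen in two blocks)")
                seen.append(contig)
            elif not seen:
                seen.append(contig)
            if read.reference_start < last.get(contig, 0):
                raise ParseError(
                    f"{sam_path}: input not coordinate-sorted at read "
                    f"{read.query_name} ({contig}:{read.reference_start + 1})")
            last[contig] = read.reference_start
            if read.mapping_quality < mapq_min:
                continue
            cig = read.cigartuples
            if cig is None:
                raise ParseError(
                    f"{sam_path}: mapped read {read.query_name} has no CIGAR")
            ev = events.setdefault(contig, {})
            pos = read.reference_start
            for op, length in cig:
                consumes = _REF_OPS.get(op)
                if consumes is None:
                    continue  # I/S/H/P: no reference advance
                if consumes:
                    ev[pos] = ev.get(pos, 0) + 1
                    ev[pos + length] = ev.get(pos + length, 0) - 1
                pos += length
    runs: List[Tuple[str, int, int, int]] = []
    for contig, ev in events.items():
        depth = 0
        prev: Optional[int] = None
        for p in sorted(ev):
            if prev is not None and depth > 0 and p > prev:
                runs.append((contig, prev, p, depth))
            depth += ev[p]
            prev = p
    return DepthTrack(runs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _gt_string(record) -> str:
    genotype = getattr(record, "genotype", None)
    zygosity = getattr(record, "zygosity", None)
    if genotype is None and zygosity is None:
        return "."
    if zygosity is None:
        sep = "|" if getattr(record, "phased", False) else "/"
        return sep.join("." if a is None else str(a) for a in genotype)
    return {HET: "0/1", HOM: "1/1", HALF: "1/."}.get(zygosity, ".")


def write_vcf(records: Iterable, path,
              contig_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write records (VariantRecord or atoms with the same surface) as VCF 4.2."""
    records = list(records)
    contigs: Dict[str, Optional[int]] = {}
    if contig_lengths:
        contigs.update(contig_lengths)
    for r in records:
        contigs.setdefault(r.contig, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contigs.items():
            if length is None:
                fh.write(f"##contig=<ID={contig}>\n")
            else:
                fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for r in records:
            alts = ",".join(getattr(r, "alts", None) or (r.alt,))
            filt = getattr(r, "filter_text", ".")
            fh.write(f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{alts}\t.\t{filt}\t.\t"
                     f"GT\t{_gt_string(r)}\n")


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for region in regions:
            fh.write(f"{region.contig}\t{region.start}\t{region.end}\n")


def write_depth_bedgraph(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for contig, s, e, d in track:
            fh.write(f"{contig}\t{s}\t{e}\t{d}\n")


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
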