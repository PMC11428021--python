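"""Depth stratification of the genome and of variants.

Available read depth affects both precision and recall, so global metrics
generalize poorly to datasets with different depth characteristics.  The
genome is therefore quantized into depth strata — by default low (0-9),
medium (10-30) and high (>30) read depth, with depth computed from reads of
mapping quality >= 60 — intersected with the confident regions (and, for
capture data, the target regions), and every metric is reported per stratum.

Note the low stratum deliberately conflates regions with few reads and
regions full of low-MAPQ reads (high mapping uncertainty); there is no
separate MAPQ stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .formats import DepthTrack, RegionSet

DEFAULT_MAPQ_MIN = 60


@dataclass(frozen=True)
class Stratum:
    """A named half-open depth interval ``[low, high)``; ``high=None`` is open."""

    name: str
    low: int
    high: Optional[int]

    def contains(self, depth: int) -> bool:
        return depth >= self.low and (self.high is None or depth < self.high)


@dataclass(frozen=True)
class StratumScheme:
    """Ordered depth strata covering all non-negative depths without gaps."""

    strata: Tuple[Stratum, ...] = (
        Stratum("low", 0, 10),
        Stratum("medium", 10, 31),
        Stratum("high", 31, None),
    )
    mapq_min: int = DEFAULT_MAPQ_MIN

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("scheme needs at least one stratum")
        if self.strata[0].low != 0:
            raise ValueError("strata must start at depth 0")
        for a, b in zip(self.strata, self.strata[1:]):
            if a.high != b.low:
                raise ValueError(
                    f"strata {a.name} and {b.name} are not contiguous")
        if self.strata[-1].high is not None:
            raise ValueError("last stratum must be open-ended")
        names = [s.name for s in self.strata]
        if len(set(names)) != len(names):
            raise ValueError("stratum names must be unique")

    @property
    def names(self) -> List[str]:
        return [s.name for s in self.strata]

    def stratum_of(self, depth: int) -> str:
        for s in self.strata:
            if s.contains(depth):
                return s.name
        raise AssertionError("contiguous strata cover all depths")

    @classmethod
    def from_string(cls, text: str, mapq_min: int = DEFAULT_MAPQ_MIN) -> "StratumScheme":
        """Parse e.g. ``"0-9,10-30,>30"`` (inclusive bounds, last open-ended).

        Three strata get the conventional names low/medium/high; otherwise
        strata are named ``d<low>-<high>``.
        """
        parts = [p.strip() for p in text.split(",") if p.strip()]
        bounds: List[Tuple[int, Optional[int]]] = []
        for p in parts:
            if p.startswith(">"):
                bounds.append((int(p[1:]) + 1, None))
            else:
                lo, hi = p.split("-")
                bounds.append((int(lo), int(hi) + 1))
        if len(bounds) == 3:
            names = ["low", "medium", "high"]
        else:
            names = [f"d{lo}-{hi - 1}" if hi is not None else f"d{lo}+"
                     for lo, hi in bounds]
        return cls(strata=tuple(Stratum(n, lo, hi)
                                for n, (lo, hi) in zip(names, bounds)),
                   mapq_min=mapq_min)


@dataclass
class StratifiedRegions:
    """Mapping stratum name -> RegionSet; strata are pairwise disjoint."""

    scheme: StratumScheme
    regions: Dict[str, RegionSet] = field(default_factory=dict)

    def __getitem__(self, name: str) -> RegionSet:
        return self.regions.get(name, RegionSet())

    def names(self) -> List[str]:
        return self.scheme.names

    def assign(self, contig: str, pos0: int) -> Optional[str]:
        for name in self.scheme.names:
            if self[name].contains(contig, pos0):
                return name
        return None


def quantize(depth: DepthTrack, scheme: StratumScheme,
             contig_lengths: Optional[Mapping[str, int]] = None) -> StratifiedRegions:
    """Assign every base to the stratum containing its depth.

    Bases not covered by any run — including whole contigs listed only in
    ``contig_lengths`` — have depth 0 and land in the first stratum.  Output
    RegionSets are maximally merged.
    """
    per_stratum: Dict[str, List[Tuple[str, int, int]]] = {n: [] for n in scheme.names}
    zero = scheme.stratum_of(0)
    contigs = set(depth.contigs())
    if contig_lengths:
        contigs |= set(contig_lengths)
    for contig in sorted(contigs):
        cursor = 0
        for s, e, d in depth.runs(contig):
            if s > cursor:
                per_stratum[zero].append((contig, cursor, s))
            per_stratum[scheme.stratum_of(d)].append((contig, s, e))
            cursor = e
        if contig_lengths and contig in contig_lengths:
            length = contig_lengths[contig]
            if cursor < length:
                per_stratum[zero].append((contig, cursor, length))
    return StratifiedRegions(
        scheme=scheme,
        regions={n: RegionSet(per_stratum[n]) for n in scheme.names})


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    """Exact interval intersection of two region sets."""
    return a.intersect(b)


def build_strata(depth: DepthTrack, scheme: StratumScheme,
                 confident: RegionSet,
                 target: Optional[RegionSet] = None,
                 contig_lengths: Optional[Mapping[str, int]] = None) -> StratifiedRegions:
    """Quantize depth, then restrict to confident (and target) regions.

    For capture data, ``target`` further restricts the evaluation to the
    captured loci; otherwise the strata partition the confident regions.
    """
    strata = quantize(depth, scheme, contig_lengths)
    scope = confident if target is None else confident.intersect(target)
    return StratifiedRegions(
        scheme=scheme,
        regions={n: strata[n].intersect(scope) for n in scheme.names})


def assign_stratum(variant, strata: StratifiedRegions) -> Optional[str]:
    """Stratum of a variant by the 0-based position of its first REF base.

    A single anchor-base rule: variants spanning a stratum boundary are
    assigned to the stratum of their anchor and never duplicated.  Returns
    None for variants outside all strata (excluded from evaluation).
    """
    return strata.assign(variant.contig, variant.pos0)


def split_by_stratum(variants: Sequence, strata: StratifiedRegions) -> Dict[Optional[str], List]:
    """Partition variants by stratum; key None collects out-of-scope ones."""
    out: Dict[Optional[str], List] = {n: [] for n in strata.names()}
    out[None] = []
    for v in variants:
        out[assign_stratum(v, strata)].append(v)
    return out
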