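"""Haplotype-aware matching of a query callset against a truth set.

Nearby atoms are grouped into *superloci* (transitive closure of a 30 bp
gap), and within each superlocus the comparator replays subsets of atoms
onto the reference to build diplotypes — unordered pairs of haplotype
sequences implied by the genotypes.  A query subset matches a truth subset
when their diplotypes are equal over the superlocus window.  The comparator
selects the assignment maximizing matched truth atoms (then matched query
atoms, then genotype-concordant pairs, then smallest matched position set,
for determinism); unmatched query atoms become FP, unmatched truth atoms FN.

Two modes:

* ``genotyping`` — atom placement is constrained by the called zygosity
  (het on exactly one haplotype, hom on both, half-calls on one), so a
  het/hom swap is an error (FP + FN).
* ``calling`` — placement is relaxed to presence on at least one haplotype
  (ploidy-squashed), so a het/hom swap still matches, with
  ``genotype_concordant=False`` recording the wrong zygosity.

Duplicate query alleles (same atom from several source records, surviving
deduplication with different genotypes) all count as TP when their allele
is matched in the truth — the reason the query-side TP count can exceed the
truth-side one.

Superloci with more distinct alleles per side than the enumeration cap
(default 8) fall back to exact allele matching and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .formats import Callset
from .normalize import AtomicVariant
from .stratify import StratifiedRegions, assign_stratum

DEFAULT_GAP = 30
DEFAULT_CAP = 8

MODES = ("genotyping", "calling")


@dataclass(frozen=True)
class MatchAnnotation:
    """Per-atom match outcome on one side of the comparison."""

    variant: AtomicVariant
    side: str                     # "query" | "truth"
    status: str                   # TP | FP (query) | FN (truth)
    genotype_concordant: Optional[bool] = None
    matched_partner_ids: Tuple[str, ...] = ()
    stratum: Optional[str] = None
    fallback: bool = False


@dataclass
class Superlocus:
    """A window of nearby query and truth atoms matched jointly."""

    contig: str
    start0: int
    end0: int
    query: List[AtomicVariant] = field(default_factory=list)
    truth: List[AtomicVariant] = field(default_factory=list)


def cluster_superloci(query: Sequence[AtomicVariant],
                      truth: Sequence[AtomicVariant],
                      gap: int = DEFAULT_GAP) -> List[Superlocus]:
    """Group atoms within ``gap`` bases (transitive closure) per contig."""
    tagged = [(a, "query") for a in query] + [(a, "truth") for a in truth]
    tagged.sort(key=lambda t: (t[0].contig, t[0].pos0, t[0].end0))
    out: List[Superlocus] = []
    for atom, side in tagged:
        if (out and out[-1].contig == atom.contig
                and atom.pos0 <= out[-1].end0 + gap):
            sl = out[-1]
            sl.end0 = max(sl.end0, atom.end0)
        else:
            sl = Superlocus(atom.contig, atom.pos0, atom.end0)
            out.append(sl)
        (sl.query if side == "query" else sl.truth).append(atom)
    return out


# ---------------------------------------------------------------------------
# diplotype enumeration
# ---------------------------------------------------------------------------

_PLACEMENTS = {
    "het": (frozenset({0}), frozenset({1})),
    "half": (frozenset({0}), frozenset({1})),
    "hom": (frozenset({0, 1}),),
    None: (frozenset({0}), frozenset({1}), frozenset({0, 1})),
}
_ANY = (frozenset({0}), frozenset({1}), frozenset({0, 1}))


def _group_alleles(atoms: Sequence[AtomicVariant]):
    """Collapse atom instances to distinct alleles with allowed placements."""
    groups: Dict[Tuple[int, str, str], List[AtomicVariant]] = {}
    for a in atoms:
        groups.setdefault((a.pos0, a.ref, a.alt), []).append(a)
    return groups


def _placements_for(instances: Sequence[AtomicVariant], mode: str):
    if mode == "calling":
        return _ANY
    allowed = []
    for inst in instances:
        for p in _PLACEMENTS[inst.zygosity]:
            if p not in allowed:
                allowed.append(p)
    return tuple(allowed)


def _overlaps(a: Tuple[int, str, str], b: Tuple[int, str, str]) -> bool:
    sa, ea = a[0], a[0] + len(a[1])
    sb, eb = b[0], b[0] + len(b[1])
    return sa < eb and sb < ea


def _enumerate_assignments(atoms: Sequence[AtomicVariant], mode: str,
                           window: Tuple[str, int, int]):
    """Yield (diplotype, selected allele keys) over all consistent assignments.

    A diplotype is the sorted pair of haplotype sequences over the window.
    Assignments placing overlapping alleles on the same haplotype are skipped.
    """
    seq, start0, end0 = window
    groups = _group_alleles(atoms)
    keys = sorted(groups)
    options = [(key, (None,) + _placements_for(groups[key], mode)) for key in keys]
    results = []

    def rec(idx: int, hap_edits: Tuple[List, List]):
        if idx == len(options):
            haps = []
            for edits in hap_edits:
                s = seq[start0:end0]
                for pos0, ref, alt in sorted(edits, reverse=True):
                    off = pos0 - start0
                    s = s[:off] + alt + s[off + len(ref):]
                haps.append(s)
            diplo = tuple(sorted(haps))
            results.append((diplo, frozenset(
                k for k, p in zip(keys, placements) if p is not None)))
            return
        key, choices = options[idx]
        for choice in choices:
            placements[idx] = choice
            if choice is not None:
                ok = True
                for h in choice:
                    if any(_overlaps(key, other) for other in hap_edits[h]):
                        ok = False
                        break
                if not ok:
                    continue
                for h in choice:
                    hap_edits[h].append(key)
                rec(idx + 1, hap_edits)
                for h in choice:
                    hap_edits[h].pop()
            else:
                rec(idx + 1, hap_edits)

    placements: List = [None] * len(options)
    rec(0, ([], []))
    return results


def _zyg_eq(a: Optional[str], b: Optional[str]) -> bool:
    return a is not None and a == b


def replay_match(sl: Superlocus, reference: Mapping[str, str],
                 mode: str, cap: int = DEFAULT_CAP) -> List[MatchAnnotation]:
    """Match one superlocus by diplotype replay (see module docstring)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    q_groups = _group_alleles(sl.query)
    t_groups = _group_alleles(sl.truth)
    if len(q_groups) > cap or len(t_groups) > cap:
        return fallback_exact_match(sl)
    seq = reference[sl.contig]
    # one base of context on each side, clipped to the contig
    start0 = max(0, sl.start0 - 1)
    end0 = min(len(seq), sl.end0 + 1)
    window = (seq, start0, end0)

    truth_assignments: Dict[Tuple[str, str], List[FrozenSet]] = {}
    for diplo, sel in _enumerate_assignments(sl.truth, mode, window):
        truth_assignments.setdefault(diplo, []).append(sel)

    best = None
    best_key = None
    for diplo, q_sel in _enumerate_assignments(sl.query, mode, window):
        for t_sel in truth_assignments.get(diplo, ()):
            n_t = sum(len(t_groups[k]) for k in t_sel)
            n_q = sum(len(q_groups[k]) for k in q_sel)
            n_conc = 0
            for k in q_sel & t_sel:
                t_zyg = t_groups[k][0].zygosity
                n_conc += sum(1 for qi in q_groups[k] if _zyg_eq(qi.zygosity, t_zyg))
            pos_key = tuple(sorted(k[0] for k in q_sel | t_sel))
            key = (-n_t, -n_q, -n_conc, pos_key, diplo)
            if best_key is None or key < best_key:
                best_key = key
                best = (q_sel, t_sel)
    assert best is not None  # empty selections always match each other
    q_sel, t_sel = best
    return _annotate(sl, q_groups, t_groups, q_sel, t_sel, mode)


def _annotate(sl, q_groups, t_groups, q_sel, t_sel, mode) -> List[MatchAnnotation]:
    t_alleles = set(t_sel)
    q_alleles = set(q_sel)
    t_tp_keys = {k for k in t_groups if k in t_sel or k in q_alleles}
    q_tp_keys = {k for k in q_groups if k in q_sel or k in t_alleles}
    t_tp_ids = [inst.uid for k in sorted(t_tp_keys) for inst in t_groups[k]]
    q_tp_ids = [inst.uid for k in sorted(q_tp_keys) for inst in q_groups[k]]
    out: List[MatchAnnotation] = []
    for k in sorted(q_groups):
        for inst in q_groups[k]:
            if k in q_tp_keys:
                partners = tuple(i.uid for i in t_groups.get(k, []) if k in t_tp_keys)
                if partners:
                    t_zyg = t_groups[k][0].zygosity
                    conc: Optional[bool] = _zyg_eq(inst.zygosity, t_zyg)
                else:
                    # matched through an equivalent decomposition: in
                    # genotyping mode diplotype equality certifies the
                    # genotypes collectively; in calling mode per-atom
                    # concordance is undefined
                    partners = tuple(t_tp_ids)
                    conc = True if mode == "genotyping" else None
                out.append(MatchAnnotation(inst, "query", "TP", conc, partners))
            else:
                out.append(MatchAnnotation(inst, "query", "FP"))
    for k in sorted(t_groups):
        for inst in t_groups[k]:
            if k in t_tp_keys:
                partners = tuple(i.uid for i in q_groups.get(k, []) if k in q_tp_keys)
                if partners:
                    conc = any(_zyg_eq(q.zygosity, inst.zygosity)
                               for q in q_groups.get(k, []))
                else:
                    partners = tuple(q_tp_ids)
                    conc = True if mode == "genotyping" else None
                out.append(MatchAnnotation(inst, "truth", "TP", conc, partners))
            else:
                out.append(MatchAnnotation(inst, "truth", "FN"))
    return out


def fallback_exact_match(sl: Superlocus) -> List[MatchAnnotation]:
    """Exact (pos, ref, alt) matching for over-cap superloci; flagged."""
    q_groups = _group_alleles(sl.query)
    t_groups = _group_alleles(sl.truth)
    out: List[MatchAnnotation] = []
    for k in sorted(q_groups):
        for inst in q_groups[k]:
            if k in t_groups:
                t_zyg = t_groups[k][0].zygosity
                out.append(MatchAnnotation(
                    inst, "query", "TP", _zyg_eq(inst.zygosity, t_zyg),
                    tuple(i.uid for i in t_groups[k]), fallback=True))
            else:
                out.append(MatchAnnotation(inst, "query", "FP", fallback=True))
    for k in sorted(t_groups):
        for inst in t_groups[k]:
            if k in q_groups:
                conc = any(_zyg_eq(q.zygosity, inst.zygosity) for q in q_groups[k])
                out.append(MatchAnnotation(
                    inst, "truth", "TP", conc,
                    tuple(i.uid for i in q_groups[k]), fallback=True))
            else:
                out.append(MatchAnnotation(inst, "truth", "FN", fallback=True))
    return out


def match_callset(query: Callset, truth: Callset,
                  reference: Mapping[str, str],
                  strata: StratifiedRegions,
                  gap: int = DEFAULT_GAP,
                  cap: int = DEFAULT_CAP) -> Dict[str, List[MatchAnnotation]]:
    """Match normalized query atoms against normalized truth in both modes.

    Atoms outside all strata (outside the confident/target scope) are
    excluded before matching — out-of-scope query calls are ignored, not
    counted FP.  Each annotation carries its atom's stratum.
    """
    q_strat = {a.uid: assign_stratum(a, strata) for a in query.records}
    t_strat = {a.uid: assign_stratum(a, strata) for a in truth.records}
    q_atoms = [a for a in query.records if q_strat[a.uid] is not None]
    t_atoms = [a for a in truth.records if t_strat[a.uid] is not None]
    superloci = cluster_superloci(q_atoms, t_atoms, gap)
    results: Dict[str, List[MatchAnnotation]] = {m: [] for m in MODES}
    for mode in MODES:
        for sl in superloci:
            for ann in replay_match(sl, reference, mode, cap):
                stratum = (q_strat if ann.side == "query" else t_strat)[ann.variant.uid]
                results[mode].append(
                    MatchAnnotation(ann.variant, ann.side, ann.status,
                                    ann.genotype_concordant,
                                    ann.matched_partner_ids, stratum,
                                    ann.fallback))
    return results
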