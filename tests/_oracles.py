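"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — exhaustive enumeration and direct
string surgery — and shares no code with the package's own algorithms, so
agreement between the two is informative.
"""

from itertools import product


def apply_edit(seq: str, pos1: int, ref: str, alt: str) -> str:
    """Apply one (1-based pos, ref, alt) replacement to a sequence."""
    i = pos1 - 1
    assert seq[i:i + len(ref)] == ref, (pos1, ref, seq[i:i + len(ref)])
    return seq[:i] + alt + seq[i + len(ref):]


def leftmost_representation(seq: str, pos1: int, ref: str, alt: str,
                            max_len: int = 12):
    """Smallest-position trimmed representation of an edit, by enumeration.

    Enumerates every (pos, ref-length) candidate; the alt is implied by the
    requirement that applying the candidate reproduces the edited sequence.
    Among equivalent representations, picks the minimal position, then the
    shortest alleles.  Returns (pos, ref, alt).
    """
    target = apply_edit(seq, pos1, ref, alt)
    delta = len(target) - len(seq)
    best = None
    for p in range(1, len(seq) + 1):
        for rl in range(0, max_len + 1):
            if p - 1 + rl > len(seq):
                continue
            al = rl + delta
            if al < 0 or al > max_len:
                continue
            cand_ref = seq[p - 1:p - 1 + rl]
            cand_alt = target[p - 1:p - 1 + al]
            if seq[:p - 1] + cand_alt + seq[p - 1 + rl:] != target:
                continue
            if rl == 0 or al == 0:
                continue  # only VCF-style non-empty alleles
            if cand_ref == cand_alt:
                continue
            # trimmed: no shared last base unless one allele is exhausted,
            # no shared first base unless an anchor is required
            if cand_ref[-1] == cand_alt[-1] and min(rl, al) > 1:
                continue
            if cand_ref[0] == cand_alt[0] and min(rl, al) > 1:
                continue
            key = (p, rl + al)
            if best is None or key < best[0]:
                best = (key, (p, cand_ref, cand_alt))
    assert best is not None
    return best[1]


def all_alignments(a: str, b: str):
    """All global alignments of a vs b as column lists ((i|None, j|None))."""
    out = []

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            out.append(list(cols))
            return
        if i < len(a) and j < len(b):
            cols.append((i, j))
            rec(i + 1, j + 1, cols)
            cols.pop()
        if i < len(a):
            cols.append((i, None))
            rec(i + 1, j, cols)
            cols.pop()
        if j < len(b):
            cols.append((None, j))
            rec(i, j + 1, cols)
            cols.pop()

    rec(0, 0, [])
    return out


def best_alignment(a: str, b: str):
    """Max-scoring alignment (match +1, mismatch -1, gap -2), leftmost gaps."""
    def score(cols):
        s = 0
        for i, j in cols:
            if i is None or j is None:
                s -= 2
            else:
                s += 1 if a[i] == b[j] else -1
        return s

    def gap_positions(cols):
        return tuple(k for k, (i, j) in enumerate(cols) if i is None or j is None)

    aligns = all_alignments(a, b)
    top = max(score(c) for c in aligns)
    return min((c for c in aligns if score(c) == top), key=gap_positions)


# ---------------------------------------------------------------------------
# haplotype replay oracle
# ---------------------------------------------------------------------------

_PLACE = {"het": ({0}, {1}), "half": ({0}, {1}), "hom": ({0, 1},),
          None: ({0}, {1}, {0, 1})}


def _apply_to_hap(window: str, start0: int, alleles) -> str:
    s = window
    for pos0, ref, alt in sorted(alleles, reverse=True):
        off = pos0 - start0
        assert s[off:off + len(ref)] == ref
        s = s[:off] + alt + s[off + len(ref):]
    return s


def _side_assignments(atoms, mode, window, start0):
    """Every (diplotype, selected allele keys) for one side, via product."""
    groups = {}
    for atom in atoms:
        groups.setdefault((atom.pos0, atom.ref, atom.alt), []).append(atom)
    keys = sorted(groups)
    per_key_choices = []
    for k in keys:
        if mode == "calling":
            placements = ({0}, {1}, {0, 1})
        else:
            placements = []
            for inst in groups[k]:
                for p in _PLACE[inst.zygosity]:
                    if p not in placements:
                        placements.append(p)
        per_key_choices.append([None] + list(placements))
    results = []
    for combo in product(*per_key_choices):
        haps = ([], [])
        ok = True
        for k, place in zip(keys, combo):
            if place is None:
                continue
            for h in place:
                for other in haps[h]:
                    if k[0] < other[0] + len(other[1]) and other[0] < k[0] + len(k[1]):
                        ok = False
                if not ok:
                    break
                haps[h].append(k)
            if not ok:
                break
        if not ok:
            continue
        diplo = tuple(sorted(_apply_to_hap(window, start0, h) for h in haps))
        sel = frozenset(k for k, p in zip(keys, combo) if p is not None)
        results.append((diplo, sel, groups))
    return results, groups


def oracle_match_counts(sl, reference, mode):
    """(tp_query, tp_truth, fp, fn) for one superlocus by full enumeration.

    Searches every pair of side assignments with equal diplotypes, using the
    same preference order as the comparator (max matched truth instances,
    then query instances, then concordant pairs, then smallest positions).
    """
    seq = reference[sl.contig]
    start0 = max(0, sl.start0 - 1)
    end0 = min(len(seq), sl.end0 + 1)
    window = seq[start0:end0]
    q_assign, q_groups = _side_assignments(sl.query, mode, window, start0)
    t_assign, t_groups = _side_assignments(sl.truth, mode, window, start0)
    best_key, best = None, None
    for qd, q_sel, _ in q_assign:
        for td, t_sel, _ in t_assign:
            if qd != td:
                continue
            n_t = sum(len(t_groups[k]) for k in t_sel)
            n_q = sum(len(q_groups[k]) for k in q_sel)
            n_conc = 0
            for k in q_sel & t_sel:
                tz = t_groups[k][0].zygosity
                n_conc += sum(1 for qi in q_groups[k]
                              if qi.zygosity is not None and qi.zygosity == tz)
            pos_key = tuple(sorted(k[0] for k in q_sel | t_sel))
            key = (-n_t, -n_q, -n_conc, pos_key, qd)
            if best_key is None or key < best_key:
                best_key, best = key, (q_sel, t_sel)
    q_sel, t_sel = best
    tp_query = sum(len(v) for k, v in q_groups.items()
                   if k in q_sel or k in t_sel)
    tp_truth = sum(len(v) for k, v in t_groups.items()
                   if k in t_sel or k in q_sel)
    fp = sum(len(v) for v in q_groups.values()) - tp_query
    fn = sum(len(v) for v in t_groups.values()) - tp_truth
    return tp_query, tp_truth, fp, fn
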