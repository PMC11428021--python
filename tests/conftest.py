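import numpy as np
import pytest

from varbench.formats import HET, HOM
from varbench.normalize import AtomicVariant
from varbench.synth import CallsetSim, SimConfig, generate_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small complete benchmark fixture with three labelled callsets."""
    d = tmp_path_factory.mktemp("fixture")
    cfg = SimConfig(
        seed=11, truth_count=150,
        callsets=[CallsetSim(id=f"cs{i}",
                             labels={"caller": "XY"[i % 2], "mapper": f"m{i % 2}"})
                  for i in range(3)])
    generate_fixture(cfg, d)
    return d


def make_atom(pos, ref, alt, zyg=HET, contig="c", uid=None, source="s"):
    return AtomicVariant(contig=contig, pos=pos, ref=ref, alt=alt,
                         zygosity=zyg, source_id=source,
                         uid=uid or f"{source}:{pos}:{ref}>{alt}:{zyg}")


def random_superlocus_atoms(rng: np.random.Generator, seq: str):
    """Random query/truth atom lists (<= 4 per side) over one sequence.

    Truth atoms are sampled first; query atoms either copy a truth atom
    (possibly with flipped zygosity) or are novel, so all TP/FP/FN outcomes
    occur.
    """
    def sample_atoms(side, n, base_atoms=()):
        atoms, used = [], []
        base = list(base_atoms)
        for k in range(n):
            if base and rng.random() < 0.6:
                src = base[int(rng.integers(len(base)))]
                zyg = src.zygosity if rng.random() < 0.7 else \
                    (HOM if src.zygosity == HET else HET)
                atoms.append(make_atom(src.pos, src.ref, src.alt, zyg,
                                       uid=f"{side}{k}", source=side))
                used.append((src.pos0, src.end0))
                continue
            for _ in range(30):
                pos = int(rng.integers(5, len(seq) - 6)) + 1
                kind = rng.integers(3)
                if kind == 0:
                    ref = seq[pos - 1]
                    alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(3))) % 4]
                    if alt == ref:
                        continue
                elif kind == 1:
                    ref = seq[pos - 1]
                    alt = ref + "ACGT"[int(rng.integers(4))]
                else:
                    ref = seq[pos - 1:pos + 1]
                    alt = seq[pos - 1]
                span = (pos - 1, pos - 1 + len(ref))
                if any(s < span[1] and span[0] < e for s, e in used):
                    continue
                used.append(span)
                zyg = HET if rng.random() < 0.6 else HOM
                atoms.append(make_atom(pos, ref, alt, zyg,
                                       uid=f"{side}{k}", source=side))
                break
        return atoms

    truth = sample_atoms("t", int(rng.integers(0, 5)))
    query = sample_atoms("q", int(rng.integers(0, 5)), truth)
    return query, truth


def random_reference(rng: np.random.Generator, length=60, contig="c"):
    return {contig: "".join("ACGT"[i] for i in rng.integers(0, 4, length))}
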