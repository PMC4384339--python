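import numpy as np
import pytest

import fmmap as fm

TOY_TEXT = "AGGAGC"
TOY_S = [6, 3, 0, 5, 2, 4, 1]
TOY_R = [2, 6, 4, 1, 5, 3, 0]
TOY_B = "CG$GGAA"
TOY_C = (0, 2, 3, 6)


@pytest.fixture(scope="session")
def toy_index():
    """Index of the worked-example reference with default compression."""
    return fm.build_index(TOY_TEXT)


@pytest.fixture(scope="session")
def toy_index_r2():
    """Same reference, SA/ISA sampled every 2 positions."""
    return fm.build_index(TOY_TEXT, r=2)


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_occurrences(text: str, pattern: str) -> set[int]:
    return {
        i for i in range(len(text) - len(pattern) + 1)
        if text[i : i + len(pattern)] == pattern
    }


def random_instance(rng, ref_lo=300, ref_hi=2000, read_lo=25, read_hi=80,
                    e_max=3, mutation_rate=0.03, indel_fraction=0.4):
    """One (reference, read, e) study instance: a read sampled from a random
    reference with injected mutations, or occasionally an unrelated read."""
    n = int(rng.integers(ref_lo, ref_hi + 1))
    ref = fm.generate_reference(n, int(rng.integers(1 << 30)))
    L = int(rng.integers(read_lo, read_hi + 1))
    e = int(rng.integers(0, e_max + 1))
    if rng.random() < 0.85:
        params = fm.SimParams(
            n_reads=1, read_length=L, mutation_rate=mutation_rate,
            indel_fraction=indel_fraction, seed=int(rng.integers(1 << 30)),
        )
        read = fm.generate_reads(ref, params)[0].sequence
    else:
        read = fm.generate_reference(L, int(rng.integers(1 << 30)))
    return ref, read, e


class SweepResult:
    """Outcome of the mapper-vs-oracle sweep, shared between tests."""

    def __init__(self):
        self.n_instances = 0
        self.disagreements = []
        self.counters = {}  # raw mapping emissions / duplicates for e <= 2


@pytest.fixture(scope="session")
def lossless_sweep():
    """>= 200 random instances (references 1-5 kb, reads 30-100 bp, e <= 3,
    unlimited stack): run search_complete, search_prototype and the DP oracle
    on each and record disagreements and duplicate emissions."""
    rng = np.random.default_rng(20240901)
    sweep = SweepResult()
    for _ in range(200):
        ref, read, e = random_instance(
            rng, ref_lo=1000, ref_hi=5000, read_lo=30, read_hi=100, e_max=3,
            mutation_rate=0.02, indel_fraction=0.3,
        )
        idx = fm.build_index(ref)
        config = fm.SearchConfig(max_errors=e, segsize=7)
        counters = sweep.counters if e <= 2 else None
        complete = {
            m.position for m in fm.search_complete(idx, read, config, counters=counters)
        }
        proto = {m.position for m in fm.search_prototype(idx, read, e, config)}
        oracle = {p for p, _ in fm.brute_force_map(ref, read, e)}
        sweep.n_instances += 1
        if not (complete == proto == oracle):
            sweep.disagreements.append(
                dict(read=read, e=e, complete=complete, proto=proto, oracle=oracle)
            )
    return sweep
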