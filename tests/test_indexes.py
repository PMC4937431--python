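import json
import math

import numpy as np
import pytest

from biobit import (
    BBParams,
    GenomeSequence,
    biobit,
    biobit_argmax,
    components,
    compute_indexes,
    double_logarithmic_length,
    generate_random_genome,
    logarithmic_length,
    random_entropy_gap_bound,
)


def test_logarithmic_lengths():
    assert logarithmic_length(4) == 1.0
    assert double_logarithmic_length(4) == 2.0
    assert double_logarithmic_length(1_000) == pytest.approx(9.97, abs=0.005)
    assert double_logarithmic_length(1_000_000) == pytest.approx(19.93, abs=0.005)
    with pytest.raises(ValueError):
        logarithmic_length(1)


def test_components_boundaries_and_conservation():
    n = 4096
    lg = logarithmic_length(n)
    ec, ac, ok = components(2 * lg, n)   # hypothetical random limit
    assert (ec, ac) == (lg, 0.0) and not ok
    ec, ac, ok = components(lg, n)
    assert (ec, ac) == (0.0, lg) and not ok
    ec, ac, ok = components(1.5 * lg, n)
    assert ok and ec + ac == pytest.approx(lg, abs=1e-12)


def test_random_genome_anti_entropy_negligible(random_1e6):
    ix = compute_indexes(random_1e6)
    slack = random_entropy_gap_bound(1_000_000)
    # AC of a random genome is at the scale of the theoretical gap bound
    assert ix.ac < 50 * slack  # 50 * 2.7e-5 ~ 1.4e-3 bits, still ~0 vs LG ~ 10
    assert ix.af < 0.001


@pytest.mark.parametrize("text, expected_lx", [
    ("a" * 4096, 4096 - 11),  # k = 2LG = 12, one distinct word, W = n-k+1
])
def test_lexical_index_maximally_repetitive(text, expected_lx):
    ix = compute_indexes(GenomeSequence.from_text(text))
    assert ix.lx == pytest.approx(expected_lx)


def test_lexical_index_random_limit(random_1e6):
    ix = compute_indexes(random_1e6)
    assert 1.0 <= ix.lx < 1.05


def test_lexical_index_never_below_one(random_1e4):
    for g in (random_1e4,
              GenomeSequence.from_text("acgt" * 300),
              generate_random_genome(500, 9)):
        assert compute_indexes(g).lx >= 1.0 - 1e-12


def test_biobit_shape():
    assert biobit(0.0, 10.0) == 0.0
    assert biobit(0.5, 10.0) == 0.0
    with pytest.raises(ValueError):
        biobit(-0.1, 10.0)
    # unique interior maximum at gamma / (2 gamma + 2 delta)
    params = BBParams()
    grid = np.linspace(0, 0.5, 200_001)
    vals = grid ** params.gamma * (1 - 2 * grid) ** params.delta
    argmax = grid[np.argmax(vals)]
    assert biobit_argmax(params) == pytest.approx(1 / 14, abs=1e-9)
    assert argmax == pytest.approx(biobit_argmax(params), abs=1e-3)


@pytest.mark.parametrize("gamma, delta", [(0.5, 3.0), (1.0, 1.0), (0.25, 4.0)])
def test_biobit_argmax_matches_grid(gamma, delta):
    params = BBParams(gamma=gamma, delta=delta, scale=1.0)
    grid = np.linspace(1e-9, 0.5, 100_001)
    vals = [biobit(x, 1.0, params) for x in grid]
    assert grid[int(np.argmax(vals))] == pytest.approx(
        biobit_argmax(params), abs=1e-3)


def test_biobit_super_ordered_flagged_nonpositive():
    assert biobit(0.6, 10.0) <= 0.0


def test_indexes_conservation_and_interval():
    for g in (generate_random_genome(5000, 1),
              GenomeSequence.from_text("acgt" * 4000),
              generate_random_genome(65536, 2)):
        ix = compute_indexes(g)
        assert ix.ec + ix.ac == pytest.approx(ix.lg, abs=1e-9)
        assert ix.two_lg == pytest.approx(2 * ix.lg, abs=1e-12)
        assert ix.af == pytest.approx(ix.ac / ix.lg, abs=1e-12)
        assert ix.eh == pytest.approx(1 - 2 * ix.af, abs=1e-9)


def test_period4_genome_super_ordered():
    # "acgt" tiled: at k ~ 2LG only 4 distinct words exist -> AF ~ max, BB ~ 0
    g = GenomeSequence.from_text("acgt" * (2 ** 16))
    ix = compute_indexes(g)
    assert ix.af > 0.7
    assert ix.bb <= 0.0  # (1 - 2 AF) factor collapses
    assert ix.lx > 1000


def test_indexes_invariant_under_run_permutation():
    rng = np.random.default_rng(0)
    runs = tuple("".join(rng.choice(list("acgt"), size=400)) for _ in range(5))
    a = compute_indexes(GenomeSequence(runs))
    b = compute_indexes(GenomeSequence(runs[::-1]))
    for f in ("e_2lg", "ec", "ac", "lx", "af", "eh", "bb"):
        assert getattr(a, f) == pytest.approx(getattr(b, f), abs=1e-12)


def test_bb_ordering_semantics(random_1e4):
    # genomes are ordered by their biobit value
    near_opt = compute_indexes(GenomeSequence.from_text(
        "acgt" * 40 + generate_random_genome(9840, 4).runs[0]))
    rnd = compute_indexes(random_1e4)
    assert rnd.bb < near_opt.bb


def test_serialization_table_order(tiny, tmp_path):
    ix = compute_indexes(generate_random_genome(1000, 5))
    tsv = ix.to_tsv()
    assert tsv.splitlines()[0].split("\t") == list(
        ("LG", "EC", "AC", "LX", "AF", "EH", "BB"))
    d = json.loads(ix.to_json())
    assert d["n"] == 1000
    assert d["ec"] + d["ac"] == pytest.approx(d["lg"])
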