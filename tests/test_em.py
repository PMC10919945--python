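import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snvem.em import (
    EMConfig,
    LearnerModel,
    aggregate_pileups,
    call_candidates,
    e_step,
    initialize_model,
    load_model_json,
    m_step,
    posterior_entropy,
    run_em,
    save_model_json,
)
from snvem.genotypes import (
    ALLELE_FRACTION,
    GENOTYPE_INDEX,
    HOM_REF_CLASS,
    N_CLASSES,
)
from snvem.pileup import LearnerSpec, LocusPileup
from tests.conftest import brute_force_posterior


def make_pileup(counts, ref_base="A", pos=0, contig="ctg"):
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim == 1:
        counts = counts[None, :]
    return LocusPileup(
        contig=contig,
        pos=pos,
        ref_base=ref_base,
        counts=counts,
        depth=int(counts.sum()),
    )


def noiseless_model(n_learners=1, pi=None):
    """Error-free emissions: allele fractions are the exact emission law."""
    theta = np.broadcast_to(ALLELE_FRACTION, (n_learners, N_CLASSES, 4)).copy()
    if pi is None:
        pi = np.full((4, N_CLASSES), 0.1)
    return LearnerModel(theta=theta, pi=pi)


# ---------------------------------------------------------------------------
# initialization


def test_initialize_homozygous_emissions():
    m = initialize_model(2, EMConfig(init_epsilon=0.05))
    k = GENOTYPE_INDEX["AA"]
    assert m.theta[0, k, 0] == pytest.approx(0.95)
    assert np.allclose(m.theta[0, k, 1:], 0.05 / 3)


def test_initialize_heterozygous_emissions():
    m = initialize_model(1, EMConfig(init_epsilon=0.05))
    k = GENOTYPE_INDEX["AC"]
    assert m.theta[0, k, 0] == pytest.approx(0.475)
    assert m.theta[0, k, 1] == pytest.approx(0.475)
    assert m.theta[0, k, 2] == pytest.approx(0.025)
    assert m.theta[0, k, 3] == pytest.approx(0.025)


def test_initialize_priors_concentrate_on_hom_ref():
    m = initialize_model(1, EMConfig(prior_hom_ref=0.998))
    g = 2  # ref base G
    assert m.pi[g, HOM_REF_CLASS[g]] == pytest.approx(0.998)
    off = np.delete(m.pi[g], HOM_REF_CLASS[g])
    assert np.allclose(off, 0.002 / 9)
    m.validate()


# ---------------------------------------------------------------------------
# E-step


def test_e_step_noiseless_three_ref_reads():
    # error-free single learner, uniform prior, counts {A:3} on ref A:
    # q(AA) = 1/(1 + 3*0.125) = 8/11, the three A-containing hets get 1/11
    post = e_step([make_pileup([3, 0, 0, 0])], noiseless_model())[0]
    assert post.probs[GENOTYPE_INDEX["AA"]] == pytest.approx(8 / 11, abs=1e-9)
    for het in ("AC", "AG", "AT"):
        assert post.probs[GENOTYPE_INDEX[het]] == pytest.approx(1 / 11, abs=1e-9)
    assert post.probs[GENOTYPE_INDEX["CC"]] == pytest.approx(0.0, abs=1e-9)
    assert post.decided == GENOTYPE_INDEX["AA"]


def test_e_step_zero_depth_returns_prior_row():
    cfg = EMConfig()
    model = initialize_model(1, cfg)
    post = e_step([make_pileup([0, 0, 0, 0], ref_base="A")], model)[0]
    assert np.allclose(post.probs, model.pi[0], atol=1e-12)


def test_e_step_invariant_under_learner_permutation():
    rng = np.random.default_rng(3)
    theta = rng.dirichlet(np.ones(4), size=(3, N_CLASSES))
    pi = rng.dirichlet(np.ones(N_CLASSES), size=4)
    counts = rng.integers(0, 5, size=(3, 4))
    perm = [2, 0, 1]
    p1 = e_step([make_pileup(counts)], LearnerModel(theta=theta, pi=pi))[0]
    p2 = e_step(
        [make_pileup(counts[perm])], LearnerModel(theta=theta[perm], pi=pi)
    )[0]
    assert np.allclose(p1.probs, p2.probs, atol=1e-12)


def test_e_step_matches_brute_force_on_enumerated_instances():
    """Oracle equivalence: all count patterns up to depth 4, 1-2 learners,
    against plain-Python Bayes enumeration, to 1e-10."""
    rng = np.random.default_rng(7)
    models = []
    for L in (1, 2):
        theta = rng.dirichlet(np.ones(4) * 2, size=(L, N_CLASSES))
        pi = rng.dirichlet(np.ones(N_CLASSES), size=4)
        models.append(LearnerModel(theta=theta, pi=pi))

    def all_counts(depth_max, L):
        cells = 4 * L
        for total in range(depth_max + 1):
            for cuts in itertools.combinations_with_replacement(range(cells), total):
                v = np.zeros(cells, dtype=int)
                for c in cuts:
                    v[c] += 1
                yield v.reshape(L, 4)

    for model in models:
        L = model.n_learners
        patterns = list(all_counts(4, L))
        for ref_idx, ref_base in enumerate("ACGT"):
            # batch of up to 3 loci exercises the aggregation path as well
            for chunk_start in range(0, len(patterns), 3):
                chunk = patterns[chunk_start : chunk_start + 3]
                piles = [
                    make_pileup(c, ref_base=ref_base, pos=i)
                    for i, c in enumerate(chunk)
                ]
                posts = e_step(piles, model)
                for c, post in zip(chunk, posts):
                    expected = brute_force_posterior(
                        c.tolist(), ref_idx, model.theta.tolist(), model.pi.tolist()
                    )
                    assert np.allclose(post.probs, expected, atol=1e-10)


def test_doubling_counts_preserves_argmax_under_uniform_prior():
    # q(k) prop. to prod theta^n; squaring the likelihood cannot change the
    # maximizer when the prior is flat
    rng = np.random.default_rng(11)
    model = noiseless_model(n_learners=2)
    model.theta = rng.dirichlet(np.ones(4) * 3, size=(2, N_CLASSES))
    for _ in range(50):
        counts = rng.integers(0, 6, size=(2, 4))
        if counts.sum() == 0:
            continue
        p1 = e_step([make_pileup(counts)], model)[0]
        p2 = e_step([make_pileup(counts * 2)], model)[0]
        assert p1.decided == p2.decided


# ---------------------------------------------------------------------------
# M-step


def test_m_step_weighted_count_arithmetic():
    # q1 = delta(AA) with learner-0 counts {A:4}; q2 = delta(AC) with
    # {A:2, C:2}: unsmoothed rows are (1,0,0,0) and (.5,.5,0,0)
    piles = [make_pileup([4, 0, 0, 0]), make_pileup([2, 2, 0, 0], pos=1)]
    posts = e_step(piles, noiseless_model())
    for post, cls in zip(posts, ("AA", "AC")):
        post.probs = np.zeros(N_CLASSES)
        post.probs[GENOTYPE_INDEX[cls]] = 1.0
    model = m_step(piles, posts, EMConfig(pseudocount=1e-6))
    assert np.allclose(model.theta[0, GENOTYPE_INDEX["AA"]], [1, 0, 0, 0], atol=1e-5)
    assert np.allclose(model.theta[0, GENOTYPE_INDEX["AC"]], [0.5, 0.5, 0, 0], atol=1e-5)
    # classes with no posterior mass fall back to the uniform pseudocount row
    assert np.allclose(model.theta[0, GENOTYPE_INDEX["GG"]], 0.25, atol=1e-6)


def test_m_step_huge_pseudocount_flattens_emissions():
    piles = [make_pileup([5, 1, 0, 0])]
    posts = e_step(piles, noiseless_model())
    model = m_step(piles, posts, EMConfig(pseudocount=1e9))
    assert np.allclose(model.theta, 0.25, atol=1e-6)


def test_m_step_keeps_rows_for_silent_learner():
    # learner 1 has zero observations everywhere: its confusion is kept
    counts = np.array([[3, 0, 0, 0], [0, 0, 0, 0]])
    piles = [make_pileup(counts)]
    init = initialize_model(2, EMConfig())
    posts = e_step(piles, init)
    model = m_step(piles, posts, EMConfig(), model=init)
    assert np.allclose(model.theta[1], init.theta[1])
    assert not np.allclose(model.theta[0], init.theta[0])


# ---------------------------------------------------------------------------
# full EM


def random_instance(rng, n_loci=None, n_learners=None):
    n_loci = n_loci or int(rng.integers(1, 30))
    n_learners = n_learners or int(rng.integers(1, 3))
    piles = []
    for i in range(n_loci):
        counts = rng.integers(0, 8, size=(n_learners, 4))
        ref = "ACGT"[rng.integers(0, 4)]
        piles.append(make_pileup(counts, ref_base=ref, pos=i))
    return piles, LearnerSpec(tuple(range(0, n_learners * 10, 10)))


def test_em_objective_monotone_on_random_instances():
    # the smoothed (MAP) EM guarantees a non-decreasing penalized
    # objective; the raw likelihood trace is recorded but may dip when the
    # smoothing mass is large relative to a tiny instance
    rng = np.random.default_rng(12345)
    for _ in range(100):
        piles, spec = random_instance(rng)
        res = run_em(piles, spec, EMConfig(max_iters=25))
        obj = np.array(res.objective_trace)
        assert (np.diff(obj) >= -1e-8 * np.abs(obj[:-1])).all()
        assert len(res.loglik_trace) == len(obj)


def test_run_em_single_iteration_is_one_e_m_pass():
    rng = np.random.default_rng(5)
    piles, spec = random_instance(rng, n_loci=10, n_learners=2)
    cfg = EMConfig(max_iters=1)
    res = run_em(piles, spec, cfg)
    assert res.n_iters == 1 and not res.converged
    init = initialize_model(2, cfg)
    manual = m_step(piles, e_step(piles, init), cfg, model=init)
    assert np.allclose(res.model.theta, manual.theta, atol=1e-12)
    assert np.allclose(res.model.pi, manual.pi, atol=1e-12)


def test_run_em_posteriors_normalized_with_bounded_entropy():
    rng = np.random.default_rng(8)
    piles, spec = random_instance(rng, n_loci=40, n_learners=2)
    res = run_em(piles, spec, EMConfig())
    for post in res.posteriors:
        assert post.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= post.entropy_bits <= np.log2(10) + 1e-12
        assert post.decided == int(np.argmax(post.probs))


def test_pattern_aggregation_is_exact():
    # duplicated (ref, counts) patterns must produce identical posteriors
    piles = [make_pileup([3, 1, 0, 0], pos=i) for i in range(5)]
    piles += [make_pileup([0, 4, 0, 0], ref_base="C", pos=5 + i) for i in range(3)]
    agg = aggregate_pileups(piles, 1)
    assert agg.n_patterns == 2
    assert agg.mult.sum() == 8
    model = initialize_model(1, EMConfig())
    posts = e_step(piles, model)
    assert np.allclose(posts[0].probs, posts[4].probs)
    assert np.allclose(posts[5].probs, posts[7].probs)


def test_em_recovers_planted_confusion_matrices():
    # sample counts from a known model; the EM estimate of the homozygous
    # diagonal must approach the planted per-learner accuracy
    rng = np.random.default_rng(99)
    err = np.array([0.05, 0.005])
    theta_true = np.empty((2, N_CLASSES, 4))
    for j in range(2):
        for k in range(N_CLASSES):
            clean = ALLELE_FRACTION[k]
            theta_true[j, k] = clean * (1 - err[j]) + (1 - clean[:, None]).T[0] * 0
            theta_true[j, k] = clean * (1 - err[j]) + err[j] * (1 - clean) / (
                (1 - clean).sum()
            )
    piles = []
    for i in range(20_000):
        ref_idx = rng.integers(0, 4)
        k = HOM_REF_CLASS[ref_idx] if rng.random() < 0.998 else rng.integers(0, N_CLASSES)
        counts = np.stack(
            [rng.multinomial(15, theta_true[j, k]) for j in range(2)]
        )
        piles.append(make_pileup(counts, ref_base="ACGT"[ref_idx], pos=i))
    res = run_em(piles, LearnerSpec((0, 20)), EMConfig())
    for j in range(2):
        for k in range(4):  # homozygous classes are abundant -> tight
            assert res.model.theta[j, k, k] == pytest.approx(
                theta_true[j, k, k], abs=0.01
            )


# ---------------------------------------------------------------------------
# decisions, candidates, entropy


def test_candidates_emitted_iff_genotype_differs_from_reference():
    piles = [
        make_pileup([10, 10, 0, 0], ref_base="A", pos=0),  # het AC
        make_pileup([20, 0, 0, 0], ref_base="A", pos=1),  # hom ref
        make_pileup([0, 20, 0, 0], ref_base="A", pos=2),  # hom alt CC
    ]
    model = noiseless_model(pi=np.full((4, N_CLASSES), 0.1))
    posts = e_step(piles, model)
    cands = call_candidates(posts, piles)
    assert [(c.pos, c.genotype) for c in cands] == [(0, "AC"), (2, "CC")]
    assert cands[0].is_het and not cands[1].is_het
    assert cands[0].alt_fraction == pytest.approx(0.5)
    assert cands[1].alt_fraction == pytest.approx(1.0)


@pytest.mark.parametrize(
    "probs,expected",
    [
        (np.full(10, 0.1), np.log2(10)),
        (np.eye(10)[3], 0.0),
        (np.array([0.5, 0.5] + [0.0] * 8), 1.0),
    ],
)
def test_posterior_entropy_reference_values(probs, expected):
    assert posterior_entropy(probs) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=10, max_size=10))
def test_posterior_entropy_bounds(raw):
    p = np.array(raw)
    p /= p.sum()
    h = posterior_entropy(p)
    assert -1e-12 <= h <= np.log2(10) + 1e-12


def test_model_json_round_trip(tmp_path):
    model = initialize_model(3, EMConfig())
    path = tmp_path / "model.json"
    save_model_json(model, path, EMConfig(), loglik_trace=[-10.0, -9.5])
    loaded = load_model_json(path)
    assert np.allclose(loaded.theta, model.theta)
    assert np.allclose(loaded.pi, model.pi)
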