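"""Unsupervised EM over pileups: learner confusion matrices, class priors,
per-locus genotype posteriors.

The model is a Dawid–Skene-style multi-class label-aggregation model. Each
learner j has a 10x4 confusion matrix theta[j, k, b]: the probability that
it emits nucleotide b at a locus whose true diploid genotype is class k.
Class priors pi[r, k] are conditioned on the reference base r, so
"homozygous reference" is the high-prior class at every locus regardless of
reference composition. With n[i, j, b] the observation counts at locus i,

    q_i(k)  proportional to  pi[r_i, k] * prod_{j,b} theta[j, k, b]^n[i,j,b]

is the genotype posterior (E-step); the M-step re-estimates theta and pi
from posterior-weighted counts with Dirichlet-style pseudocount smoothing.
Loci with identical (ref_base, counts) patterns have identical posteriors,
so the fit collapses them with multiplicities — an exact speedup.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from snvem.genotypes import (
    ALLELE_FRACTION,
    BASE_INDEX,
    GENOTYPE_ALLELES,
    HOM_REF_CLASS,
    IS_HET,
    N_CLASSES,
)
from snvem.pileup import LearnerSpec, LocusPileup
from snvem.variants import CandidateVariant

LOG2 = np.log(2.0)
#: probability floor guaranteed by pseudocount smoothing
EPS_MIN = 1e-12


class EMDivergenceError(RuntimeError):
    """Raised when the observed-data log-likelihood becomes non-finite."""


@dataclass(frozen=True)
class EMConfig:
    """EM hyperparameters.

    tol is the relative change in the fitting objective below which the
    iteration stops; pseudocount is the Dirichlet smoothing mass added per
    nucleotide cell of every confusion row (and per class of every prior
    row); init_epsilon is the emission error mass of the structured
    initialization; prior_hom_ref is the initial prior mass on the
    homozygous-reference class.
    """

    max_iters: int = 50
    tol: float = 1e-6
    init_epsilon: float = 0.05
    pseudocount: float = 0.1
    prior_hom_ref: float = 0.998
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not 0.0 < self.init_epsilon < 0.5:
            raise ValueError("init_epsilon must lie in (0, 0.5)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


@dataclass
class LearnerModel:
    """EM parameters: confusion tensor theta (L,10,4) and priors pi (4,10)."""

    theta: np.ndarray
    pi: np.ndarray

    def validate(self) -> None:
        if self.theta.ndim != 3 or self.theta.shape[1:] != (N_CLASSES, 4):
            raise ValueError(f"theta has wrong shape {self.theta.shape}")
        if self.pi.shape != (4, N_CLASSES):
            raise ValueError(f"pi has wrong shape {self.pi.shape}")
        if not np.allclose(self.theta.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("theta rows do not sum to 1")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pi rows do not sum to 1")
        if (self.theta < EPS_MIN).any() or (self.pi < EPS_MIN).any():
            raise ValueError("probability entries below floor")

    @property
    def n_learners(self) -> int:
        return self.theta.shape[0]

    def to_dict(self) -> dict:
        return {"theta": self.theta.tolist(), "pi": self.pi.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "LearnerModel":
        m = cls(theta=np.asarray(d["theta"], float), pi=np.asarray(d["pi"], float))
        m.validate()
        return m


@dataclass
class ClassPosterior:
    """Posterior over the ten genotype classes at one locus."""

    contig: str
    pos: int
    probs: np.ndarray  # 10-vector, sums to 1
    decided: int  # argmax, ties broken toward the lowest class index
    entropy_bits: float


@dataclass
class EMResult:
    model: LearnerModel
    posteriors: list[ClassPosterior]
    loglik_trace: list[float]
    objective_trace: list[float]
    n_iters: int
    converged: bool
    warnings: list[str] = field(default_factory=list)


def posterior_entropy(probs: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector (0*log 0 := 0)."""
    p = np.asarray(probs, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / LOG2)


def initialize_model(n_learners: int, config: EMConfig | None = None) -> LearnerModel:
    """Structured initialization.

    Homozygous class (x,x): emission 1-eps on x, eps/3 on each other base.
    Heterozygous class (x,y): (1-eps)/2 on each of x and y, eps/2 on each
    other base. Priors put prior_hom_ref on the homozygous-reference class
    and spread the remainder uniformly over the other nine.
    """
    config = config or EMConfig()
    eps = config.init_epsilon
    row = np.zeros((N_CLASSES, 4))
    for k, (a, b) in enumerate(GENOTYPE_ALLELES):
        if a == b:
            row[k, :] = eps / 3.0
            row[k, a] = 1.0 - eps
        else:
            row[k, :] = eps / 2.0
            row[k, a] = (1.0 - eps) / 2.0
            row[k, b] = (1.0 - eps) / 2.0
    theta = np.broadcast_to(row, (n_learners, N_CLASSES, 4)).copy()

    p0 = config.prior_hom_ref
    pi = np.full((4, N_CLASSES), (1.0 - p0) / (N_CLASSES - 1))
    for r in range(4):
        pi[r, HOM_REF_CLASS[r]] = p0
    model = LearnerModel(theta=theta, pi=pi)
    model.validate()
    return model


# ---------------------------------------------------------------------------
# pattern aggregation


@dataclass
class PatternData:
    """Pileups collapsed to unique (ref_base, counts) patterns."""

    counts: np.ndarray  # (P, L, 4) float
    ref_idx: np.ndarray  # (P,)
    mult: np.ndarray  # (P,) multiplicity of each pattern
    inverse: np.ndarray  # (N,) locus -> pattern row

    @property
    def n_patterns(self) -> int:
        return len(self.mult)


def aggregate_pileups(pileups: Sequence[LocusPileup], n_learners: int) -> PatternData:
    n = len(pileups)
    if n == 0:
        raise ValueError("no pileups to aggregate")
    flat = np.empty((n, 1 + n_learners * 4), dtype=np.int64)
    for i, p in enumerate(pileups):
        flat[i, 0] = BASE_INDEX[p.ref_base]
        flat[i, 1:] = p.counts.ravel()
    uniq, inverse, mult = np.unique(flat, axis=0, return_inverse=True, return_counts=True)
    return PatternData(
        counts=uniq[:, 1:].reshape(-1, n_learners, 4).astype(float),
        ref_idx=uniq[:, 0].astype(np.int64),
        mult=mult.astype(float),
        inverse=inverse.ravel(),
    )


def _pattern_posteriors(
    patterns: PatternData, model: LearnerModel
) -> tuple[np.ndarray, float]:
    """Posterior q (P,10) per pattern and total observed-data log-likelihood."""
    L = model.n_learners
    # floor avoids 0 * -inf for boundary models with exact-zero emissions
    log_theta = np.log(np.maximum(model.theta, EPS_MIN))  # (L,10,4)
    # (P, L*4) @ (L*4, 10): per-class log emission likelihood of each pattern
    ll = patterns.counts.reshape(-1, L * 4) @ log_theta.transpose(1, 0, 2).reshape(
        N_CLASSES, L * 4
    ).T
    log_q = np.log(np.maximum(model.pi, EPS_MIN))[patterns.ref_idx] + ll
    norm = logsumexp(log_q, axis=1)
    q = np.exp(log_q - norm[:, None])
    total_ll = float(patterns.mult @ norm)
    return q, total_ll


def _log_prior_penalty(model: LearnerModel, pseudocount: float) -> float:
    """Dirichlet log-prior term of the MAP objective (up to a constant)."""
    return float(
        pseudocount * (np.log(model.theta).sum() + np.log(model.pi).sum())
    )


def e_step(
    pileups: Sequence[LocusPileup], model: LearnerModel
) -> list[ClassPosterior]:
    """Per-locus genotype posteriors under a fixed model.

    A locus with all-zero counts gets the prior row of its reference base.
    """
    patterns = aggregate_pileups(pileups, model.n_learners)
    q, _ = _pattern_posteriors(patterns, model)
    return _expand_posteriors(pileups, patterns, q)


def _expand_posteriors(
    pileups: Sequence[LocusPileup], patterns: PatternData, q: np.ndarray
) -> list[ClassPosterior]:
    decided = q.argmax(axis=1)  # first (lowest-index) argmax on ties
    ent = np.array([posterior_entropy(q[p]) for p in range(q.shape[0])])
    out = []
    for i, pile in enumerate(pileups):
        p = patterns.inverse[i]
        out.append(
            ClassPosterior(
                contig=pile.contig,
                pos=pile.pos,
                probs=q[p],
                decided=int(decided[p]),
                entropy_bits=float(ent[p]),
            )
        )
    return out


def _m_step_patterns(
    patterns: PatternData,
    q: np.ndarray,
    prev: LearnerModel,
    pseudocount: float,
    warnings: list[str],
) -> LearnerModel:
    w = q * patterns.mult[:, None]  # (P,10) posterior-weighted multiplicities
    num = np.einsum("pk,pjb->jkb", w, patterns.counts) + pseudocount
    theta = num / num.sum(axis=2, keepdims=True)

    # learner with zero retained observations anywhere: keep previous row
    obs_per_learner = (patterns.counts.sum(axis=2) * patterns.mult[:, None]).sum(axis=0)
    for j in np.nonzero(obs_per_learner == 0)[0]:
        theta[j] = prev.theta[j]
        warnings.append(f"learner {j}: no observations, confusion matrix kept")

    pi = prev.pi.copy()
    for r in range(4):
        sel = patterns.ref_idx == r
        if not sel.any():
            warnings.append(f"ref base {'ACGT'[r]}: no loci, prior row kept")
            continue
        s = w[sel].sum(axis=0) + pseudocount
        pi[r] = s / s.sum()
    model = LearnerModel(theta=theta, pi=pi)
    model.validate()
    return model


def m_step(
    pileups: Sequence[LocusPileup],
    posteriors: Sequence[ClassPosterior],
    config: EMConfig | None = None,
    model: LearnerModel | None = None,
) -> LearnerModel:
    """Re-estimate theta and pi from posterior-weighted counts."""
    config = config or EMConfig()
    if len(pileups) != len(posteriors):
        raise ValueError("pileups and posteriors must align 1:1")
    n_learners = pileups[0].counts.shape[0]
    prev = model or initialize_model(n_learners, config)
    patterns = PatternData(
        counts=np.stack([p.counts for p in pileups]).astype(float),
        ref_idx=np.array([BASE_INDEX[p.ref_base] for p in pileups]),
        mult=np.ones(len(pileups)),
        inverse=np.arange(len(pileups)),
    )
    q = np.stack([p.probs for p in posteriors])
    return _m_step_patterns(patterns, q, prev, config.pseudocount, warnings=[])


def run_em(
    pileups: Sequence[LocusPileup],
    learner_spec: LearnerSpec | None = None,
    config: EMConfig | None = None,
) -> EMResult:
    """Fit the ensemble model by EM and return per-locus posteriors.

    The convergence monitor is the MAP objective (observed-data
    log-likelihood plus the Dirichlet smoothing prior), which the smoothed
    M-step provably does not decrease; the raw log-likelihood is recorded
    alongside it in the trace.
    """
    if len(pileups) == 0:
        raise ValueError("run_em requires at least one pileup")
    config = config or EMConfig()
    learner_spec = learner_spec or LearnerSpec()
    n_learners = pileups[0].counts.shape[0]
    if n_learners != learner_spec.n_learners:
        raise ValueError("pileup learner dimension does not match learner_spec")

    patterns = aggregate_pileups(pileups, n_learners)
    model = initialize_model(n_learners, config)
    warnings: list[str] = []
    ll_trace: list[float] = []
    obj_trace: list[float] = []
    converged = False
    q = None
    for it in range(config.max_iters):
        q, ll = _pattern_posteriors(patterns, model)
        if not np.isfinite(ll):
            raise EMDivergenceError(
                f"non-finite log-likelihood at iteration {it}: {ll}"
            )
        obj = ll + _log_prior_penalty(model, config.pseudocount)
        ll_trace.append(ll)
        obj_trace.append(obj)
        if it > 0 and abs(obj - obj_trace[-2]) <= config.tol * abs(obj_trace[-2]):
            converged = True
            break
        model = _m_step_patterns(patterns, q, model, config.pseudocount, warnings)

    # posteriors under the final model
    q, _ = _pattern_posteriors(patterns, model)
    posteriors = _expand_posteriors(pileups, patterns, q)
    return EMResult(
        model=model,
        posteriors=posteriors,
        loglik_trace=ll_trace,
        objective_trace=obj_trace,
        n_iters=len(ll_trace),
        converged=converged,
        warnings=warnings,
    )


def call_candidates(
    posteriors: Sequence[ClassPosterior], pileups: Sequence[LocusPileup]
) -> list[CandidateVariant]:
    """Mark SNV candidates: loci whose decided genotype differs from the
    reference in at least one allele."""
    if len(posteriors) != len(pileups):
        raise ValueError("posteriors and pileups must align 1:1")
    out: list[CandidateVariant] = []
    for post, pile in zip(posteriors, pileups):
        if post.decided == HOM_REF_CLASS[BASE_INDEX[pile.ref_base]]:
            continue
        out.append(
            CandidateVariant(
                contig=pile.contig,
                pos=pile.pos,
                ref_base=pile.ref_base,
                decided=post.decided,
                depth=pile.depth,
                alt_fraction=pile.alt_fraction(),
                entropy_bits=post.entropy_bits,
                posterior=post.probs,
            )
        )
    return out


def save_model_json(
    model: LearnerModel,
    path: str | Path,
    config: EMConfig | None = None,
    loglik_trace: Sequence[float] | None = None,
) -> None:
    """Persist the fitted model (documented JSON schema, version 1)."""
    payload = {
        "schema": "snvem.learner_model/1",
        "model": model.to_dict(),
        "config": asdict(config) if config else None,
        "loglik_trace": list(loglik_trace) if loglik_trace is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model_json(path: str | Path) -> LearnerModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "snvem.learner_model/1":
        raise ValueError(f"unrecognized model schema in {path}")
    return LearnerModel.from_dict(payload["model"])
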