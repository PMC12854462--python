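"""Reinforcement-learning hyper-parameter optimization.

Two Gaussian policies — a 3-vector policy over the negative-mixture raw
logits and a scalar policy over the fusion-weight logit — are updated with
the REINFORCE score-function rule. Raw Gaussian samples are projected onto
their constrained spaces (softmax onto the simplex for α, logistic into
(0, 1) for k_emb); the projection is treated as part of the environment so
the printed Gaussian score gradient stays exact. The reward for a candidate
is the relative gain in cross-modal clustering agreement: the ARI between
labelings obtained by clustering the image-modality and gene-modality
embeddings separately, compared against the current model.

Training alternates every epoch between updating α (even epochs) and k_emb
(odd epochs): per epoch, candidate hyper-parameters are sampled, the model
is trained one epoch per candidate from a shared snapshot, the best-reward
candidate's weights are kept, and the policy mean moves along the
reward-weighted score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .tuple_contrast import AlphaMixture

logger = logging.getLogger(__name__)

BASELINE_EPS = 1e-6


@dataclass
class PolicyState:
    """Gaussian policy parameters for the two tuned hyper-parameters."""

    mu_alpha: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mu_k: float = 0.0
    sigma_alpha: float = 0.3
    sigma_k: float = 0.3
    eta: float = 0.05
    n_candidates: int = 4

    def __post_init__(self):
        self.mu_alpha = np.asarray(self.mu_alpha, dtype=np.float64)
        if self.sigma_alpha <= 0 or self.sigma_k <= 0:
            raise ValueError("policy scales must be positive")
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")
        if self.n_candidates < 1:
            raise ValueError("need at least one candidate")

    @property
    def alpha_mean(self) -> AlphaMixture:
        return project_alpha(self.mu_alpha)

    @property
    def k_mean(self) -> float:
        return project_k(self.mu_k)


@dataclass
class RewardRecord:
    """One candidate's projected value, ARIs and relative reward."""

    candidate_value: object
    reward: float
    baseline_ari: float
    candidate_ari: float


def project_alpha(raw: np.ndarray) -> AlphaMixture:
    """Softmax projection of a raw 3-vector onto the probability simplex."""
    raw = np.asarray(raw, dtype=np.float64)
    z = raw - raw.max()
    e = np.exp(z)
    return AlphaMixture(e / e.sum())


def project_k(raw: float) -> float:
    """Logistic projection of a raw scalar into (0, 1), clamped away from the
    endpoints so downstream (0, 1) preconditions hold even when the float
    sigmoid saturates."""
    v = 1.0 / (1.0 + np.exp(-float(np.clip(raw, -500, 500))))
    return float(np.clip(v, 1e-12, 1.0 - 1e-12))


def cross_modal_ari(h_img: np.ndarray, h_ST: np.ndarray, K: int, seed: int = 0) -> float:
    """ARI between K-means labelings of the two unimodal embeddings.

    A degenerate labeling (fewer than two distinct clusters) yields 0 with a
    warning.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score

    labs = []
    for h in (h_img, h_ST):
        h = np.asarray(h, dtype=np.float64)
        if np.allclose(h, h[0]):
            logger.warning("degenerate constant embedding; cross-modal ARI set to 0")
            return 0.0
        labs.append(
            KMeans(n_clusters=K, n_init=4, random_state=seed).fit_predict(h)
        )
    if any(len(np.unique(l)) < 2 for l in labs):
        logger.warning("single-cluster labeling; cross-modal ARI set to 0")
        return 0.0
    return float(adjusted_rand_score(labs[0], labs[1]))


def modality_reward(candidate, baseline, K: int, seed: int = 0,
                    candidate_value=None) -> RewardRecord:
    """Relative cross-modal-ARI improvement of a candidate over the baseline.

    ``candidate`` / ``baseline`` either expose ``unimodal_embeddings()`` or
    are (h_ST, h_img) pairs; ``baseline`` may also be a precomputed ARI
    float. Near-zero baselines fall back to the absolute difference.
    """

    def _ari(obj) -> float:
        if isinstance(obj, (int, float)):
            return float(obj)
        if hasattr(obj, "unimodal_embeddings"):
            h_ST, h_img = obj.unimodal_embeddings()
        else:
            h_ST, h_img = obj
        return cross_modal_ari(h_img, h_ST, K, seed=seed)

    cand_ari = _ari(candidate)
    base_ari = _ari(baseline)
    if base_ari <= BASELINE_EPS:
        logger.warning(
            "baseline cross-modal ARI %.3g is non-positive; using absolute difference",
            base_ari,
        )
        reward = cand_ari - base_ari
    else:
        reward = (cand_ari - base_ari) / base_ari
    return RewardRecord(
        candidate_value=candidate_value,
        reward=float(reward),
        baseline_ari=base_ari,
        candidate_ari=cand_ari,
    )


def policy_update(
    ps: PolicyState,
    samples: Sequence,
    rewards: Sequence[float],
    which: str,
) -> PolicyState:
    """REINFORCE step on the selected Gaussian policy (σ held fixed):
    μ ← μ + η · (1/B) Σ_i R_i · (x_i − μ) / σ²."""
    if len(samples) != len(rewards):
        raise ValueError("samples and rewards must align")
    B = len(samples)
    if which == "alpha":
        grad = sum(
            r * (np.asarray(x, dtype=np.float64) - ps.mu_alpha) / ps.sigma_alpha**2
            for x, r in zip(samples, rewards)
        )
        return replace(ps, mu_alpha=ps.mu_alpha + ps.eta * grad / B)
    if which == "k":
        grad = sum(r * (float(x) - ps.mu_k) / ps.sigma_k**2 for x, r in zip(samples, rewards))
        return replace(ps, mu_k=ps.mu_k + ps.eta * grad / B)
    raise ValueError("which must be 'alpha' or 'k'")


@dataclass
class EpochAudit:
    """Per-epoch RL bookkeeping: candidates, rewards, chosen index."""

    epoch: int
    which: str
    candidate_values: list
    rewards: List[float]
    selected: int
    baseline_ari: float


def alternating_train(
    trainer,
    ps: PolicyState,
    T: int,
    rng: np.random.Generator,
    K: int,
    cluster_seed: int = 0,
) -> tuple:
    """Alternating model/hyper-parameter optimization.

    Even epochs tune the α mixture, odd epochs the fusion weight k_emb.
    Each RL epoch branches candidate models from a shared snapshot, trains
    one epoch per candidate, keeps the argmax-reward weights and applies the
    REINFORCE update. Ablation flags pin either hyper-parameter to its
    current policy mean. Returns (trainer, final policy, audit list).
    """
    if T < 2:
        raise ValueError("need at least 2 epochs to alternate")
    audits: List[EpochAudit] = []
    abl = getattr(trainer, "ablations", None)
    for t in range(1, T + 1):
        which = "alpha" if t % 2 == 0 else "k"
        fixed = abl is not None and (
            (which == "alpha" and abl.fixed_alpha) or (which == "k" and abl.fixed_kemb)
        )
        if fixed:
            trainer.train_epoch(ps.alpha_mean, ps.k_mean)
            continue

        base_ari = cross_modal_ari(
            *reversed(trainer.unimodal_embeddings()), K, seed=cluster_seed
        )
        snap = trainer.snapshot()
        # common random numbers: every candidate sees the same minibatch
        # stream, so reward differences isolate the hyper-parameter's effect
        stream_seed = int(rng.integers(2**31))
        raw_samples, rewards, cand_snaps, values = [], [], [], []
        for i in range(ps.n_candidates):
            if which == "alpha":
                raw = ps.mu_alpha + ps.sigma_alpha * rng.standard_normal(3)
                alpha, k_emb = project_alpha(raw), ps.k_mean
                value = alpha.alpha.copy()
            else:
                raw = float(ps.mu_k + ps.sigma_k * rng.standard_normal())
                alpha, k_emb = ps.alpha_mean, project_k(raw)
                value = k_emb
            trainer.restore(snap)
            trainer.rng = np.random.default_rng(stream_seed)
            trainer.train_epoch(alpha, k_emb)
            rec = modality_reward(trainer, base_ari, K, seed=cluster_seed, candidate_value=value)
            raw_samples.append(raw)
            rewards.append(rec.reward)
            values.append(value)
            cand_snaps.append(trainer.snapshot())
        best = int(np.argmax(rewards))
        trainer.restore(cand_snaps[best])
        ps = policy_update(ps, raw_samples, rewards, which)
        audits.append(
            EpochAudit(
                epoch=t,
                which=which,
                candidate_values=values,
                rewards=list(map(float, rewards)),
                selected=best,
                baseline_ari=float(base_ari),
            )
        )
    return trainer, ps, audits
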