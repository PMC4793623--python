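"""Cross-validation and ranking evaluation for the path-decay predictor.

Two leave-one-out protocols are implemented:

* **per-interaction** -- each known drug-target link is removed from the
  graph in turn; the drug's targets are re-scored and the held-out target's
  rank among *all* targets (known ones included) is recorded.
* **per-drug** ("new drug") -- all of a drug's interaction edges are
  removed at once, simulating a drug without known targets; a round is a
  top-1 hit if the best-ranked removed target sits at rank 1.

Rank-based metrics use pessimistic tie handling: among equal scores the
held-out target is placed last, so degenerate all-zero score vectors never
count as hits.  The pooled ROC treats each round's held-out link score as a
positive and the same round's non-interacting pair scores as negatives;
known pairs other than the held-out link are neither.  AUC uses the
trapezoidal/midrank convention.  A per-round-averaged AUC is available as a
switch for comparison.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .dataset_io import DTIDataset
from .hetgraph import HetGraph, ScoreParams, build_graph, interactions_removed
from .pathscore import Engine, pessimistic_rank, score_drug

logger = logging.getLogger(__name__)

TOP_KS = (1, 2, 5)

Mode = Literal["per-interaction", "per-drug", "rank-after-removal", "kfold"]


@dataclass
class LoocvRound:
    """One cross-validation round for one drug."""

    drug: str
    removed_targets: list[str]
    target_scores: np.ndarray  # aligned to dataset.target_ids
    test_rank: int  # best pessimistic rank over removed targets

    def __post_init__(self) -> None:
        if not self.removed_targets:
            raise ValueError("a round must remove at least one target")
        if not 1 <= self.test_rank <= len(self.target_scores):
            raise ValueError(f"test_rank {self.test_rank} out of range")


@dataclass
class EvaluationReport:
    """Aggregated cross-validation result.

    ``topk_pct`` maps k to the percentage of rounds whose held-out link
    ranked within the top k; ``auc`` is the pooled ROC area in [0, 1].
    """

    auc: float
    topk_pct: dict[int, float]
    n_rounds: int
    params: ScoreParams
    mode: str
    rounds: list[LoocvRound] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        ks = sorted(self.topk_pct)
        vals = [self.topk_pct[k] for k in ks]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("top-k percentages must be nondecreasing in k")
        if any(not 0.0 <= v <= 100.0 for v in vals):
            raise ValueError("top-k percentages must lie in [0, 100]")

    def summary(self) -> str:
        lines = [
            f"mode      {self.mode}",
            f"rounds    {self.n_rounds}",
            f"alpha     {self.params.alpha}",
            f"max_len   {self.params.max_len}",
            f"cutoff    {self.params.sim_cutoff}",
            f"AUC (%)   {100 * self.auc:.2f}",
        ]
        for k in sorted(self.topk_pct):
            lines.append(f"top-{k} (%) {self.topk_pct[k]:.2f}")
        return "\n".join(lines)

    def to_keyvalues(self) -> dict[str, float | int | str]:
        kv: dict[str, float | int | str] = {
            "mode": self.mode,
            "n_rounds": self.n_rounds,
            "auc": round(100 * self.auc, 2),
            "alpha": self.params.alpha,
            "max_len": self.params.max_len,
            "cutoff": self.params.sim_cutoff,
        }
        for k in sorted(self.topk_pct):
            kv[f"top{k}"] = round(self.topk_pct[k], 2)
        return kv

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, val in self.to_keyvalues().items():
                fh.write(f"{key}\t{val}\n")


def _round_for_drug(
    hg: HetGraph,
    dataset: DTIDataset,
    drug: str,
    removed: list[str],
    params: ScoreParams,
    engine: Engine,
) -> LoocvRound:
    with interactions_removed(hg, [(drug, t) for t in removed]):
        scores = score_drug(hg, drug, params, engine=engine)
    rank = removed_set_rank(scores, [dataset.target_index(t) for t in removed])
    return LoocvRound(drug, list(removed), scores, rank)


def removed_set_rank(scores: np.ndarray, removed_idx: Sequence[int]) -> int:
    """Best pessimistic rank achieved by any of the removed targets.

    Ties are resolved against the held-out set: every tied *non-removed*
    target is placed ahead, but a tied removed target can still occupy the
    next position (any deterministic tie-break would put one of them
    there).  For a single removed target this equals
    :func:`daspfind.pathscore.pessimistic_rank`.
    """
    scores = np.asarray(scores, dtype=float)
    best = scores[list(removed_idx)].max()
    n_greater = int((scores > best).sum())
    tied = scores == best
    n_tied_nonremoved = int(tied.sum()) - int(tied[list(removed_idx)].sum())
    return n_greater + n_tied_nonremoved + 1


def _report(
    rounds: list[LoocvRound],
    dataset: DTIDataset,
    params: ScoreParams,
    mode: str,
    auc_pooling: str = "pooled",
) -> EvaluationReport:
    n = len(rounds)
    topk = {
        k: round(100.0 * sum(r.test_rank <= k for r in rounds) / n, 2)
        for k in TOP_KS
    }
    auc = compute_auc(rounds, dataset, pooling=auc_pooling)
    return EvaluationReport(auc, topk, n, params, mode, rounds)


def loocv_per_interaction(
    dataset: DTIDataset,
    params: ScoreParams | None = None,
    engine: Engine = "auto",
    auc_pooling: str = "pooled",
    progress: bool = False,
) -> EvaluationReport:
    """Leave-one-interaction-out cross-validation.

    For every known link, that single edge is removed (the drug's other
    known links stay in the graph and in the ranking), the drug's targets
    are re-scored, and the held-out target's rank is recorded.
    """
    params = params or ScoreParams()
    hg = build_graph(dataset, params)
    rounds: list[LoocvRound] = []
    t0 = time.monotonic()
    pairs = dataset.interaction_pairs()
    if not pairs:
        raise ValueError("dataset has no interactions to cross-validate")
    for i, (d, t) in enumerate(pairs, start=1):
        rounds.append(_round_for_drug(hg, dataset, d, [t], params, engine))
        if progress and (i % 100 == 0 or i == len(pairs)):
            logger.info(
                "loocv %d/%d rounds, %.1fs elapsed", i, len(pairs),
                time.monotonic() - t0,
            )
    return _report(rounds, dataset, params, "per-interaction", auc_pooling)


def loocv_per_drug(
    dataset: DTIDataset,
    params: ScoreParams | None = None,
    engine: Engine = "auto",
    auc_pooling: str = "pooled",
    progress: bool = False,
) -> EvaluationReport:
    """"New drug" cross-validation: remove all of each drug's links at once.

    A round counts as a top-k hit if *any* removed target ranks within the
    top k; this matches the retrieval-of-any-known-target reading of the
    new-drug scenario.
    """
    params = params or ScoreParams()
    hg = build_graph(dataset, params)
    rounds = []
    drugs = [
        d for i, d in enumerate(dataset.drug_ids) if dataset.interactions[i].any()
    ]
    t0 = time.monotonic()
    for i, d in enumerate(drugs, start=1):
        di = dataset.drug_index(d)
        removed = [
            t for t, v in zip(dataset.target_ids, dataset.interactions[di]) if v == 1
        ]
        rounds.append(_round_for_drug(hg, dataset, d, removed, params, engine))
        if progress and (i % 50 == 0 or i == len(drugs)):
            logger.info(
                "new-drug loocv %d/%d drugs, %.1fs elapsed", i, len(drugs),
                time.monotonic() - t0,
            )
    return _report(rounds, dataset, params, "per-drug", auc_pooling)


def compute_auc(
    rounds: Sequence[LoocvRound],
    dataset: DTIDataset,
    pooling: str = "pooled",
) -> float:
    """ROC area over cross-validation rounds.

    Positives are the held-out links' scores; negatives, per round, are the
    scores of the round's drug against every target it is *not* known to
    interact with.  ``pooling="pooled"`` builds one global ROC over all
    rounds (thresholds varied globally); ``pooling="per-round"`` averages
    one ROC area per round.
    """
    if not rounds:
        raise ValueError("no rounds")
    if pooling not in ("pooled", "per-round"):
        raise ValueError(f"unknown AUC pooling {pooling!r}")
    all_labels: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    per_round: list[float] = []
    for r in rounds:
        di = dataset.drug_index(r.drug)
        known = dataset.interactions[di] == 1
        removed_idx = np.array([dataset.target_index(t) for t in r.removed_targets])
        mask = ~known
        mask[removed_idx] = True  # held-out links are the positives
        labels = np.zeros(len(dataset.target_ids), dtype=int)
        labels[removed_idx] = 1
        all_labels.append(labels[mask])
        all_scores.append(r.target_scores[mask])
        if pooling == "per-round":
            if labels[mask].all() or not labels[mask].any():
                raise ValueError(
                    f"round for drug {r.drug!r} has no negatives; AUC undefined"
                )
            per_round.append(roc_auc_score(labels[mask], r.target_scores[mask]))
    if pooling == "per-round":
        return float(np.mean(per_round))
    y = np.concatenate(all_labels)
    s = np.concatenate(all_scores)
    if y.all() or not y.any():
        raise ValueError("pooled ROC needs both positives and negatives")
    return float(roc_auc_score(y, s))


def rank_after_removing_known(round_: LoocvRound, dataset: DTIDataset) -> int:
    """Held-out link's rank among targets excluding the drug's other known
    targets (the rank-after-removal evaluation criterion).

    Only defined for per-interaction rounds (a single removed target).
    """
    if len(round_.removed_targets) != 1:
        raise ValueError("rank-after-removal applies to per-interaction rounds")
    di = dataset.drug_index(round_.drug)
    ti = dataset.target_index(round_.removed_targets[0])
    keep = dataset.interactions[di] == 0
    keep[ti] = True
    sub = round_.target_scores[keep]
    return pessimistic_rank(sub, int(keep[:ti].sum()))


def kfold_cv(
    dataset: DTIDataset,
    params: ScoreParams | None = None,
    k: int = 10,
    seed: int = 0,
    engine: Engine = "auto",
    auc_pooling: str = "pooled",
) -> EvaluationReport:
    """k-fold cross-validation over interactions.

    The known links are shuffled with the given seed and split into k
    folds; each fold is removed en bloc and every held-out link is then
    ranked exactly as in the per-interaction protocol (its fold-mates are
    absent from the graph during scoring).  ``k = n_interactions``
    reproduces leave-one-interaction-out exactly.
    """
    params = params or ScoreParams()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    pairs = dataset.interaction_pairs()
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} known interactions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    folds = np.array_split(order, k)
    hg = build_graph(dataset, params)
    rounds = []
    for fold in folds:
        held_out = [pairs[i] for i in fold]
        with interactions_removed(hg, held_out):
            for d, t in held_out:
                scores = score_drug(hg, d, params, engine=engine)
                rank = pessimistic_rank(scores, dataset.target_index(t))
                rounds.append(LoocvRound(d, [t], scores, rank))
    return _report(rounds, dataset, params, f"kfold(k={k},seed={seed})", auc_pooling)


def alpha_sweep(
    dataset: DTIDataset,
    alphas: Sequence[float],
    params: ScoreParams | None = None,
    engine: Engine = "auto",
) -> list[tuple[float, float]]:
    """Per-interaction LOOCV top-1 percentage as a function of alpha."""
    if not len(alphas):
        raise ValueError("no alpha values given")
    base = params or ScoreParams()
    out = []
    for a in alphas:
        p = ScoreParams(alpha=float(a), max_len=base.max_len, sim_cutoff=base.sim_cutoff)
        report = loocv_per_interaction(dataset, p, engine=engine)
        out.append((float(a), report.topk_pct[1]))
    return out
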