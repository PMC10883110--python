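"""Benchmark utilities: planted-pair recovery on synthetic cohorts.

The synthetic generator plants group-specific couplings with known
(state, channel-pair) coordinates, which turns the whole pipeline into a
parameter-recovery experiment: after clustering, windowed connectivity,
the statistical filter, mRMR and nested-CV wrapper selection, the
planted pairs should be the features the pipeline reports.

``run_recovery_seed`` executes the full pipeline on one strong-effect
cohort and scores three recovery properties per master seed:

* ``tfs_ok``  — every planted pair survives the Bonferroni screen of
  its planted state;
* ``rank_ok`` — every planted pair sits within the top 2 x (number of
  planted pairs) mRMR ranks of its state;
* ``ofs_ok``  — the optimal feature subset of every state is nonempty
  and contains only planted pairs of that state (no false selections —
  note that with strongly separable cohorts the parsimony rule can
  legitimately stop at a single planted pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classification import ClassifierSpec, CVConfig, nested_cv_evaluate
from .feature_selection import FeatureTable
from .microstates import match_templates
from .pipeline import PipelineConfig, run_pipeline
from .synthetic_data import make_strong_effect_config


@dataclass
class RecoveryResult:
    seed: int
    tfs_ok: bool
    rank_ok: bool
    ofs_ok: bool
    mean_accuracy: float


def recovery_pipeline_config(seed: int, n_per_group=(16, 16)) -> PipelineConfig:
    """The standard recovery run: strong-effect cohort, k fixed at the truth.

    The number of microstate classes is fixed to the generating k (its
    data-driven selection is validated separately), and the light
    logistic classifier keeps the wrapper stage quick; the planted
    effects are linear in feature space, so classifier capacity is not
    what the experiment probes.
    """
    sim = make_strong_effect_config(seed=seed, n_per_group=n_per_group)
    return PipelineConfig(
        simulate=sim,
        k_range=(sim.k_states, sim.k_states),
        n_restarts=6,
        cv=CVConfig(classifier=ClassifierSpec(name="logreg")),
        seed=seed,
    )


def run_recovery_seed(seed: int, n_per_group=(16, 16)) -> RecoveryResult:
    """Full-pipeline planted-pair recovery for one master seed."""
    cfg = recovery_pipeline_config(seed, n_per_group)
    bundle = run_pipeline(cfg)
    manifest = bundle["ground_truth"]
    group_maps = next(iter(bundle["group_templates"].values())).templates.maps
    perm = match_templates(manifest.true_templates.maps, group_maps)

    planted: dict[int, list[tuple[int, int]]] = {}
    for c in cfg.simulate.coupling:
        planted.setdefault(c.state, []).append(c.pair)

    tfs_ok = rank_ok = ofs_ok = True
    accs = []
    for true_state, pairs in planted.items():
        learned = int(perm[true_state])
        table = bundle["features"].get(learned)
        tfs = bundle["tfs"].get(learned)
        ranking = bundle["ranking"].get(learned)
        ofs = bundle["ofs"].get(learned)
        if table is None or tfs is None:
            tfs_ok = rank_ok = ofs_ok = False
            continue
        cols = [table.pair_index.index(p) for p in pairs]
        tfs_ok &= all(c in tfs.kept_columns for c in cols)
        if ranking is None or ofs is None:
            rank_ok = ofs_ok = False
            continue
        top = ranking.order[: 2 * len(cols)].tolist()
        rank_ok &= all(c in top for c in cols)
        selected = set(ofs.ofs_columns.tolist())
        ofs_ok &= bool(selected) and selected <= set(cols)
        accs.append(ofs.mean_accuracy)
    return RecoveryResult(
        seed=seed, tfs_ok=tfs_ok, rank_ok=rank_ok, ofs_ok=ofs_ok,
        mean_accuracy=float(np.mean(accs)) if accs else float("nan"),
    )


def permuted_label_accuracy(
    table: FeatureTable, order: np.ndarray, perm_seed: int, cv_seed: int = 0
) -> float:
    """Outer-CV accuracy after randomly permuting the class labels."""
    from .feature_selection import MrmrRanking

    rng = np.random.default_rng(perm_seed)
    shuffled = FeatureTable(
        values=table.values,
        labels=rng.permutation(table.labels),
        pair_index=table.pair_index,
        state=table.state,
        channel_labels=table.channel_labels,
    )
    ranking = MrmrRanking(order=np.asarray(order), scores=np.zeros(len(order)))
    cfg = CVConfig(classifier=ClassifierSpec(name="logreg"), seed=cv_seed)
    return nested_cv_evaluate(shuffled, ranking, cfg).mean_accuracy
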