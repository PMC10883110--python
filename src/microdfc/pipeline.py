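"""End-to-end orchestration: data -> microstates -> connectivity -> report.

``run_pipeline`` executes the whole analysis from one config and a single
master seed. The seed fans out deterministically to every stochastic
stage through ``numpy.random.SeedSequence`` spawning, so re-running the
same config reproduces every numeric output exactly.

Stage order:

1. ingest (or simulate) the cohort;
2. preprocess: average reference, optional wide band-pass + downsample
   for raw-rate data, then the 2-20 Hz microstate band;
3. microstate clustering: per-subject modified k-means on GFP-peak
   topographies, then group-level clustering of the pooled individual
   maps; backfit + 20-ms smoothing gives each subject a state sequence;
4. per state: concatenate the state's EEG, cut 30-s windows, estimate
   per-window MI connectivity for each group, and form the MCS-VS
   group-average difference matrix;
5. per state: statistical filter (TFS), mRMR ranking, nested-CV wrapper
   selection (OFS), classification metrics;
6. per state: build and export the OFS-based cortical network (MIFCN).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .signal_core import (
    Recording,
    apply_average_reference,
    bandpass_filter,
    compute_gfp,
    downsample,
    find_gfp_peaks,
    read_recording_text,
)
from .synthetic_data import SyntheticConfig, generate_cohort, write_cohort
from .microstates import (
    LabelSequence,
    TemplateSet,
    backfit,
    extract_segments,
    group_templates,
    match_templates,
    modified_kmeans,
    select_optimal_k,
    smooth_labels,
    write_label_sequence,
    write_template_set,
)
from .dynamic_connectivity import (
    MIEstimatorConfig,
    MIMatrixStack,
    group_average_difference,
    stack_from_windows,
    window_signal,
    write_difference_matrix,
    write_stack,
)
from .feature_selection import (
    build_feature_table,
    mrmr_rank,
    statistical_filter,
    write_feature_table,
    write_selection_report,
)
from .classification import CVConfig, nested_cv_evaluate, summarize_states
from .network_analysis import build_mifcn, default_atlas, export_network

logger = logging.getLogger("microdfc")


@dataclass
class PipelineConfig:
    """All tunables of one analysis run."""

    simulate: SyntheticConfig | None = None
    input_dir: str | None = None
    preproc_band: tuple[float, float] = (1.0, 40.0)
    microstate_band: tuple[float, float] = (2.0, 20.0)
    target_fs: float = 250.0
    k_range: tuple[int, int] = (4, 6)
    n_restarts: int = 10
    template_scope: str = "pooled"  # pooled | per_group
    smoothing_ms: float = 20.0
    window_s: float = 30.0
    mi: MIEstimatorConfig = field(default_factory=MIEstimatorConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    alpha: float = 0.01
    n_tests: int = 496
    mrmr_max: int | None = None
    out_dir: str | None = None
    save_stacks: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_dir is None:
            raise ValueError("either a simulate config or an input directory is required")
        if self.template_scope not in ("pooled", "per_group"):
            raise ValueError("template_scope must be 'pooled' or 'per_group'")

    def content_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


def _load_cohort(input_dir: str) -> list[tuple[Recording, str]]:
    paths = sorted(Path(input_dir).glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv recordings under {input_dir}")
    out = []
    for p in paths:
        rec = read_recording_text(p)
        if rec.group is None:
            raise ValueError(f"{p}: sidecar does not declare a group label")
        out.append((rec, rec.group))
    return out


def _preprocess(rec: Recording, cfg: PipelineConfig) -> Recording:
    rec = apply_average_reference(rec)
    if rec.fs > cfg.target_fs:
        rec = bandpass_filter(rec, *cfg.preproc_band)
        rec = downsample(rec, cfg.target_fs)
    rec = bandpass_filter(rec, *cfg.microstate_band)
    return apply_average_reference(rec)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory results bundle."""
    ss = np.random.SeedSequence(cfg.seed)
    stage_seed = {
        name: int(child.generate_state(1)[0] >> 1)
        for name, child in zip(
            ("cluster_individual", "cluster_group", "cv"), ss.spawn(3)
        )
    }
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": cfg.content_hash(), "seed": cfg.seed}

    # ------------------------------------------------------------------ data
    stage = "ingest"
    try:
        if cfg.simulate is not None:
            sim_cfg = cfg.simulate
            recordings, manifest = generate_cohort(sim_cfg)
            bundle["ground_truth"] = manifest
            if out_dir:
                write_cohort(recordings, manifest, out_dir / "cohort")
        else:
            recordings = _load_cohort(cfg.input_dir)
            bundle["ground_truth"] = None

        stage = "preprocess"
        processed = [(_preprocess(rec, cfg), grp) for rec, grp in recordings]
        del recordings  # the raw cohort can be large; only the filtered copy is used

        # ------------------------------------------------------ microstates
        stage = "microstates_individual"
        individual_sets: list[TemplateSet] = []
        ind_by_group: dict[str, list[TemplateSet]] = {}
        for i, (rec, grp) in enumerate(processed):
            gfp = compute_gfp(rec)
            peaks = find_gfp_peaks(gfp)
            peak_maps = rec.data[:, peaks].T
            sub_seed = stage_seed["cluster_individual"] + 7919 * i
            if cfg.k_range[0] == cfg.k_range[1]:
                k = cfg.k_range[0]
            else:
                k = select_optimal_k(
                    peak_maps, cfg.k_range, seed=sub_seed, n_restarts=cfg.n_restarts
                )
            res = modified_kmeans(
                peak_maps, k, n_restarts=cfg.n_restarts, seed=sub_seed,
                channel_labels=rec.channel_labels,
            )
            individual_sets.append(res.templates)
            ind_by_group.setdefault(grp, []).append(res.templates)

        stage = "microstates_group"
        if cfg.template_scope == "pooled":
            gres = group_templates(
                individual_sets, cfg.k_range, seed=stage_seed["cluster_group"],
                n_restarts=cfg.n_restarts,
            )
            templates_by_group = {grp: gres.templates for grp in ind_by_group}
            group_result = {"pooled": gres}
        else:
            # per-group clustering, states matched across groups by |corr|
            names = sorted(ind_by_group)
            results = {}
            for j, grp in enumerate(names):
                results[grp] = group_templates(
                    ind_by_group[grp], cfg.k_range,
                    seed=stage_seed["cluster_group"] + 977 * j,
                    n_restarts=cfg.n_restarts,
                )
            ref = names[0]
            k_ref = results[ref].templates.k
            for grp in names[1:]:
                other = results[grp].templates
                if other.k != k_ref:
                    raise ValueError(
                        f"group '{grp}' selected k={other.k} but '{ref}' selected "
                        f"k={k_ref}; rerun with a fixed k_range"
                    )
                perm = match_templates(results[ref].templates.maps, other.maps)
                other.maps = other.maps[perm]
                other.state_names = list(results[ref].templates.state_names)
            templates_by_group = {grp: results[grp].templates for grp in names}
            group_result = results
        bundle["group_templates"] = group_result
        any_templates = next(iter(templates_by_group.values()))
        state_names = any_templates.state_names
        k_states = any_templates.k
        bundle["state_names"] = state_names

        stage = "backfit"
        label_seqs: dict[str, LabelSequence] = {}
        for rec, grp in processed:
            seq = backfit(rec, templates_by_group[grp])
            label_seqs[rec.subject_id] = smooth_labels(seq, cfg.smoothing_ms)

        if out_dir:
            for grp, tset in templates_by_group.items():
                write_template_set(tset, out_dir / f"templates_{grp}.tsv")
            for sid, seq in label_seqs.items():
                write_label_sequence(seq, out_dir / f"labels_{sid}.json")

        # ----------------------------------------------------- connectivity
        stage = "connectivity"
        channel_labels = processed[0][0].channel_labels
        groups_present = sorted({grp for _, grp in processed})
        stacks: dict[int, dict[str, MIMatrixStack]] = {}
        occupancy: dict[int, dict[str, float]] = {}
        for state in range(k_states):
            stacks[state] = {}
            occupancy[state] = {}
            for grp in groups_present:
                wsets = []
                total = 0.0
                for rec, g in processed:
                    if g != grp:
                        continue
                    seg, seconds = extract_segments(rec, label_seqs[rec.subject_id], state)
                    total += seconds
                    wsets.append(
                        window_signal(seg, rec.fs, cfg.window_s, state=state,
                                      subject_id=rec.subject_id, group=grp)
                    )
                stacks[state][grp] = stack_from_windows(wsets, cfg.mi, group=grp)
                occupancy[state][grp] = total
        bundle["stacks"] = stacks
        bundle["occupancy"] = occupancy

        stage = "difference"
        diffs: dict[int, np.ndarray | None] = {}
        for state in range(k_states):
            a = stacks[state].get("MCS")
            b = stacks[state].get("VS")
            if a is None or b is None or a.n_windows == 0 or b.n_windows == 0:
                diffs[state] = None
                logger.warning("state %s: empty window stack, no difference matrix", state)
            else:
                diffs[state] = group_average_difference(a, b)
        bundle["diff"] = diffs

        if out_dir:
            for state in range(k_states):
                if cfg.save_stacks:
                    for grp, st in stacks[state].items():
                        write_stack(st, out_dir / f"mi_state{state}_{grp}", channel_labels)
                if diffs[state] is not None:
                    write_difference_matrix(
                        diffs[state], out_dir / f"diff_state{state}.csv", channel_labels
                    )

        # -------------------------------------------- features + classifier
        stage = "feature_selection"
        tables, tfs_res, rankings, ofs_res = {}, {}, {}, {}
        for state in range(k_states):
            present = [stacks[state][g] for g in groups_present if stacks[state][g].n_windows > 0]
            if len(present) < 2:
                continue
            table = build_feature_table(present, channel_labels)
            tables[state] = table
            tfs = statistical_filter(table, cfg.alpha, cfg.n_tests)
            tfs_res[state] = tfs
            if tfs.kept_columns.size == 0:
                logger.info("state %s: empty TFS, skipping ranking and CV", state)
                continue
            m = tfs.kept_columns.size if cfg.mrmr_max is None else min(
                cfg.mrmr_max, tfs.kept_columns.size
            )
            ranking = mrmr_rank(table, m=m, cfg=cfg.mi, columns=tfs.kept_columns)
            rankings[state] = ranking

            y = table.labels == cfg.cv.positive_class
            n_min = min(int(y.sum()), int((~y).sum()))
            # each outer training fold must still hold enough of both
            # classes to populate the inner folds
            inner_need = int(np.ceil(
                cfg.cv.inner_folds * cfg.cv.outer_folds / (cfg.cv.outer_folds - 1)
            ))
            if n_min < max(cfg.cv.outer_folds, inner_need):
                logger.warning("state %s: too few windows for nested CV", state)
                continue
            cv_cfg = dataclasses.replace(cfg.cv, seed=stage_seed["cv"] + state)
            row_groups = np.asarray(
                [sid for g in groups_present for sid in stacks[state][g].subject_ids]
            ) if cfg.cv.unit == "subject" else None
            res = nested_cv_evaluate(table, ranking, cv_cfg, groups=row_groups)
            res.tfs_size = tfs.kept_columns.size
            ofs_res[state] = res
        bundle["features"] = tables
        bundle["tfs"] = tfs_res
        bundle["ranking"] = rankings
        bundle["ofs"] = ofs_res

        if out_dir:
            for state, table in tables.items():
                write_feature_table(table, out_dir / f"features_state{state}.csv")
                write_selection_report(
                    table, tfs_res[state], rankings.get(state),
                    out_dir / f"selection_state{state}.json",
                )

        stage = "summary"
        if ofs_res:
            bundle["report"] = summarize_states(
                {state_names[s]: r for s, r in ofs_res.items()}
            )
        else:
            bundle["report"] = None

        # ----------------------------------------------------------- network
        stage = "network"
        atlas = default_atlas()
        networks = {}
        montage_known = all(lab.upper() in atlas.entries for lab in channel_labels)
        for state, res in ofs_res.items():
            if diffs[state] is None or not montage_known:
                continue
            table = tables[state]
            pairs = [table.pair_index[int(c)] for c in res.ofs_columns]
            net = build_mifcn(
                pairs, diffs[state], atlas, state, channel_labels,
                state_name=state_names[state],
            )
            networks[state] = net
            if out_dir:
                export_network(net, out_dir / f"mifcn_state{state}")
        bundle["networks"] = networks

        stage = "manifest"
        if out_dir:
            import scipy
            import sklearn

            manifest_payload = {
                "config_hash": bundle["config_hash"],
                "seed": cfg.seed,
                "versions": {
                    "microdfc": _pkg_version,
                    "numpy": np.__version__,
                    "scipy": scipy.__version__,
                    "scikit-learn": sklearn.__version__,
                },
                "state_names": state_names,
                "report": bundle["report"],
            }
            (out_dir / "manifest.json").write_text(
                json.dumps(manifest_payload, indent=1)
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return bundle
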