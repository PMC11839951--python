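"""Pipeline orchestration.

Runs the stages in dependency order — synthetic session, LFP envelopes,
oscillation states, variability metrics, mutual information, stimulus
features, encoding models, encoding-profile clustering — writing every
stage's table to disk so stages are independently re-runnable.  All
randomness flows from the single config seed; outputs carry the config
hash and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as _clusters
from . import encoding as _encoding
from . import information as _information
from . import lfp as _lfp
from . import states as _states
from . import stimfeat as _stimfeat
from . import synthetic as _synthetic
from . import variability as _variability

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "bin_spike_counts"]

log = logging.getLogger("statecode.workflow")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full parameterization of a pipeline run.

    The defaults describe a desk-scale session: 5 minutes at 30 Hz with
    40 units, 3 LFP channels at 1250 Hz, ten 30 s movie repeats.
    """

    seed: int = 0
    # synthetic session
    duration_s: float = 300.0
    n_units: int = 40
    trial_len_s: float = 30.0
    coupling: float = 1.0
    gamma_contrast: float = 3.0
    renewal_shape: float = 1.0
    shared_factor_strength: float = 0.2
    lfp_fs: float = 1250.0
    n_channels: int = 3
    movie_shape: tuple[int, int] = (96, 152)
    # stage toggles
    stages: dict = field(
        default_factory=lambda: {
            "synthetic": True,
            "lfp": True,
            "states": True,
            "variability": True,
            "information": True,
            "stimfeat": True,
            "encoding": True,
            "clusters": True,
        }
    )
    # states
    select_states: bool = False
    n_states: int = 3
    m_grid: tuple[int, ...] = (2, 3, 4, 5, 6)
    hmm_restarts: int = 5
    # variability
    n_boot: int = 5
    fa_m_grid: tuple[int, ...] = (1, 2, 3, 5)
    n_variability_units: int = 20
    # information
    mi_alpha: float = 1.01
    mi_max_pairs: int = 12
    mi_max_bins: int = 1000
    # encoding
    tau_s: float = 0.3
    encode_folds: int = 3
    encode_link: str = "identity"
    n_encode_units: int = 12
    lambda_grid: tuple[float, ...] = (0.1, 10.0, 1000.0)
    # clustering
    cluster_repeats: int = 30
    save_session: bool = False

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        for key in ("movie_shape", "m_grid", "fa_m_grid", "lambda_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]


def bin_spike_counts(
    spikes: list[list[np.ndarray]], trial_len_bins: int, n_trials: int, bin_s: float = 0.03
) -> np.ndarray:
    """Per-unit spike counts in session-long 30 ms bins (units x bins)."""
    n_units = len(spikes)
    n_bins = trial_len_bins * n_trials
    out = np.zeros((n_units, n_bins))
    edges = np.arange(trial_len_bins + 1) * bin_s
    for u in range(n_units):
        for tr in range(n_trials):
            c, _ = np.histogram(spikes[u][tr], bins=edges)
            out[u, tr * trial_len_bins : (tr + 1) * trial_len_bins] = c
    return out


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in dependency order.

    Returns a dict of in-memory stage artifacts; every stage also writes
    its table(s) under ``outdir``.  A stage failure raises
    :class:`StageError` naming the stage; a disabled upstream dependency
    raises before any work is done.
    """
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    on = cfg.stages
    needs = {
        "lfp": ["synthetic"],
        "states": ["lfp"],
        "variability": ["states"],
        "information": ["states"],
        "encoding": ["states", "stimfeat"],
        "clusters": ["encoding"],
    }
    for stage, deps in needs.items():
        if on.get(stage, False):
            for d in deps:
                if not on.get(d, False):
                    raise StageError(stage, f"requires disabled stage {d!r}")
    art: dict = {"config": cfg}
    timings: dict[str, float] = {}
    rng = np.random.default_rng(cfg.seed)

    def timed(name):
        t0 = time.time()

        def done():
            timings[name] = round(time.time() - t0, 3)
            log.info("stage %s finished in %.2fs", name, timings[name])

        return done

    if on.get("synthetic"):
        fin = timed("synthetic")
        try:
            sess = _synthetic.simulate_session(
                duration_s=cfg.duration_s,
                n_units=cfg.n_units,
                trial_len_s=cfg.trial_len_s,
                seed=cfg.seed,
                coupling=cfg.coupling,
                gamma_contrast=cfg.gamma_contrast,
                renewal_shape=cfg.renewal_shape,
                shared_factor_strength=cfg.shared_factor_strength,
                lfp_fs=cfg.lfp_fs,
                n_channels=cfg.n_channels,
                movie_shape=cfg.movie_shape,
            )
            art["session"] = sess
            if cfg.save_session:
                sess.save(outdir / "session")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - atomic per-stage failure
            raise StageError("synthetic", str(e)) from e
        fin()
    if on.get("lfp"):
        fin = timed("lfp")
        try:
            sess = art["session"]
            env = _lfp.band_envelopes(sess.lfp, sess.lfp_fs)
            art["envelopes"] = env
            _write(_lfp.envelopes_to_csv(env).iloc[:: max(1, env.n_bins // 1000)],
                   outdir / "envelopes_preview.csv", cfg)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("lfp", str(e)) from e
        fin()
    if on.get("states"):
        fin = timed("states")
        try:
            env = art["envelopes"]
            obs = env.to_observations()
            band_index = env.band_index()
            if cfg.select_states:
                curve = _states.select_num_states(
                    obs, cfg.m_grid, seed=cfg.seed, band_index=band_index
                )
                m = curve.selected
                _write(
                    pd.DataFrame(
                        {
                            "M": curve.m_grid,
                            "cv_ll": curve.cv_ll,
                            "lambda1": curve.lambda1,
                            "score": curve.scores,
                        }
                    ),
                    outdir / "model_selection.csv",
                    cfg,
                )
            else:
                m = cfg.n_states
            fit = _states.fit_hmm(obs, m, seed=cfg.seed, n_restarts=cfg.hmm_restarts)
            seq = _states.decode_and_label(fit, obs, band_index=band_index)
            dyn = _states.state_dynamics(seq)
            art["state_fit"], art["state_seq"], art["dynamics"] = fit, seq, dyn
            sem = seq.semantic_labels()
            _write(
                pd.DataFrame(
                    {
                        "bin": np.arange(seq.labels.size),
                        "hard_label": seq.labels,
                        "semantic_label": sem if sem is not None else "",
                    }
                ),
                outdir / "states.csv",
                cfg,
            )
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("states", str(e)) from e
        fin()
    if on.get("variability"):
        fin = timed("variability")
        try:
            sess, seq = art["session"], art["state_seq"]
            labels = seq.labels
            counts = bin_spike_counts(sess.spikes, sess.trial_len_bins, sess.n_trials)
            art["counts"] = counts
            nu = min(cfg.n_variability_units, counts.shape[0])
            sv = _variability.state_matched_shared_variance(
                counts[:nu], labels, m_grid=cfg.fa_m_grid, n_boot=cfg.n_boot, seed=cfg.seed
            )
            session_spikes = [
                np.concatenate(
                    [st + tr * sess.trial_len_bins * sess.bin_s for tr, st in enumerate(u)]
                )
                for u in sess.spikes[:nu]
            ]
            cv = _variability.state_matched_isi_cv(
                session_spikes, labels, n_boot=cfg.n_boot, seed=cfg.seed
            )
            win_states = np.stack(
                [
                    _variability.window_state_labels(
                        labels[tr * sess.trial_len_bins : (tr + 1) * sess.trial_len_bins]
                    )
                    for tr in range(sess.n_trials)
                ]
            )
            rows = []
            states_present = np.unique(labels)
            for u in range(nu):
                tc = np.stack(
                    [
                        _variability.bin_counts(
                            sess.spikes[u][tr], sess.trial_len_bins * sess.bin_s
                        )
                        for tr in range(sess.n_trials)
                    ]
                )
                ff = _variability.state_matched_fano(
                    tc, win_states, min_trials=min(10, max(2, sess.n_trials // 2)),
                    n_boot=cfg.n_boot, seed=cfg.seed + u,
                )
                for si, s in enumerate(states_present):
                    rows.append(
                        {
                            "unit_id": u,
                            "area": sess.units.loc[u, "area"],
                            "layer": sess.units.loc[u, "layer"],
                            "state": int(s),
                            "shared_variance": sv[si, u],
                            "isi_cv": cv[si, u],
                            "fano": ff[s] if s < ff.size else np.nan,
                            "n_boot": cfg.n_boot,
                        }
                    )
            df = pd.DataFrame(rows)
            art["variability"] = df
            _write(df, outdir / "variability.csv", cfg)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("variability", str(e)) from e
        fin()
    if on.get("information"):
        fin = timed("information")
        try:
            sess, seq = art["session"], art["state_seq"]
            counts = art.get("counts")
            if counts is None:
                counts = bin_spike_counts(sess.spikes, sess.trial_len_bins, sess.n_trials)
            # the Gram-matrix estimator is O(N^3); an even stride over the
            # session keeps the state-behavior MI tractable
            stride = max(1, seq.labels.size // cfg.mi_max_bins)
            rows = []
            for name, trace in sess.behavior.items():
                res = _information.state_behavior_mi(
                    seq.labels[::stride], trace[::stride], cfg.mi_alpha
                )
                rows.append({"trace": name, "raw_mi": res.raw, "norm_mi": res.normalized})
            _write(pd.DataFrame(rows), outdir / "mi_behavior.csv", cfg)
            mi = _information.trialwise_stimulus_mi(
                counts,
                sess.movie,
                seq.labels,
                sess.trial_len_bins,
                alpha=cfg.mi_alpha,
            )
            if len(mi) > cfg.mi_max_pairs:
                mi = mi.iloc[: cfg.mi_max_pairs]
            art["mi_stimulus"] = mi
            _write(mi, outdir / "mi_stimulus.csv", cfg)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("information", str(e)) from e
        fin()
    if on.get("stimfeat"):
        fin = timed("stimfeat")
        try:
            sess = art["session"]
            feats = _stimfeat.frame_feature_table(sess.movie)
            art["frame_features"] = feats
            _write(feats, outdir / "stimulus_features.csv", cfg)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("stimfeat", str(e)) from e
        fin()
    if on.get("encoding"):
        fin = timed("encoding")
        try:
            sess, seq = art["session"], art["state_seq"]
            counts = art.get("counts")
            if counts is None:
                counts = bin_spike_counts(sess.spikes, sess.trial_len_bins, sess.n_trials)
                art["counts"] = counts
            feats = art["frame_features"]
            stim = feats[["intensity", "contrast", "kurtosis", "entropy", "energy", "edges"]].to_numpy()
            stim = np.nan_to_num(stim, nan=0.0)
            stim_full = np.tile(stim, (sess.n_trials, 1))
            behav = np.column_stack([sess.behavior[n] for n in sorted(sess.behavior)])
            edges = np.floor(np.arange(sess.n_bins + 1) * sess.bin_s * sess.lfp_fs).astype(int)
            edges = np.minimum(edges, sess.lfp.shape[1])
            seg = np.maximum(np.diff(edges), 1)
            lfp_binned = (
                np.add.reduceat(sess.lfp[:, : edges[-1]], edges[:-1], axis=1) / seg
            ).T
            areas = sess.units["area"].to_numpy()

            def blocks_for(area: str) -> list[_encoding.FeatureBlock]:
                other = counts[areas != area]
                pop_other = (
                    other.mean(axis=0, keepdims=True).T
                    if other.size
                    else np.zeros((sess.n_bins, 1))
                )
                return [
                    _encoding.FeatureBlock("stimulus", "stimulus", stim_full),
                    _encoding.FeatureBlock("behavior", "behavior", behav),
                    _encoding.FeatureBlock("lfp", "internal-lfp", lfp_binned),
                    _encoding.FeatureBlock("population", "internal-population", pop_other),
                ]

            target_area = areas[0]
            in_area = np.flatnonzero(areas == target_area)
            pop_target = counts[in_area].mean(axis=0)
            pop_target = (pop_target - pop_target.mean()) / (pop_target.std() or 1.0)
            grid = np.asarray(cfg.lambda_grid)
            rows = []
            rep = _encoding.partition_contributions(
                blocks_for(target_area), pop_target, seq.labels, cfg.tau_s,
                k_folds=cfg.encode_folds, link="identity", lambda_grid=grid,
                seed=cfg.seed,
            )
            rows.append(_contrib_row("population", target_area, rep))
            unit_reports = {}
            for u in range(min(cfg.n_encode_units, counts.shape[0])):
                rep_u = _encoding.partition_contributions(
                    blocks_for(areas[u]), counts[u], seq.labels, cfg.tau_s,
                    k_folds=cfg.encode_folds, link=cfg.encode_link,
                    lambda_grid=grid, seed=cfg.seed,
                    smoothing_sd_s=0.05 if cfg.encode_link == "identity" else None,
                )
                unit_reports[int(u)] = rep_u
                rows.append(_contrib_row(f"unit_{u}", areas[u], rep_u))
            df = pd.DataFrame(rows)
            art["encoding"] = df
            art["unit_reports"] = unit_reports
            _write(df, outdir / "encoding.csv", cfg)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("encoding", str(e)) from e
        fin()
    if on.get("clusters"):
        fin = timed("clusters")
        try:
            unit_reports = art["unit_reports"]
            if len(unit_reports) < 10:
                raise ValueError(
                    "need at least 10 encoded units for clustering; "
                    f"got {len(unit_reports)} (raise n_encode_units)"
                )
            profiles, unit_ids = [], []
            for uid, rep in unit_reports.items():
                cat_r2 = {
                    c: max(rep.per_category[c].r2_full, 0.0) if c in rep.per_category else 0.0
                    for c in _clusters.PROFILE_CATEGORIES
                }
                profiles.append(_clusters.encoding_profile(cat_r2))
                unit_ids.append(uid)
            P = np.asarray(profiles)
            model = _clusters.ConsensusClustering(
                n_repeats=cfg.cluster_repeats,
                k_range=tuple(range(2, min(8, len(unit_ids)))),
                random_state=cfg.seed,
            ).fit(P)
            df = pd.DataFrame(
                {
                    "unit_id": unit_ids,
                    "cluster": model.labels_,
                    "merged_cluster": model.merged_labels_,
                    "state_context": "all",
                }
            )
            art["clusters"] = df
            _write(df, outdir / "clusters.csv", cfg)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("clusters", str(e)) from e
        fin()
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "timings_s": timings,
    }
    if "state_seq" in art:
        labels = art["state_seq"].labels
        occ = {int(s): float((labels == s).mean()) for s in np.unique(labels)}
        summary["state_occupancy"] = occ
        summary["mean_dwell_s"] = {
            int(s): float(np.mean(d)) if d.size else None
            for s, d in art["dynamics"].dwell_times.items()
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    art["summary"] = summary
    return art


def _contrib_row(target: str, area: str, rep: _encoding.ContributionReport) -> dict:
    row = {
        "target": target,
        "area": area,
        "tau_s": rep.tau_s,
        "cv_r2_full": rep.full.r2_full,
        "delta_internal": rep.delta_internal,
    }
    for cat, ev in rep.per_category.items():
        row[f"cv_r2_{cat}"] = ev.r2_full
    for s, r2 in rep.full.r2_per_state.items():
        row[f"cv_r2_state_{s}"] = r2
    return row
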