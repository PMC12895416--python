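"""End-to-end orchestration: synth -> featurize -> compress -> tica -> msm.

A run is described by a flat sectioned key-value config (INI).  One master
seed spawns a deterministic child seed per stage (SeedSequence spawning in
stage order), every stage writes its outputs plus a manifest entry, and a
rerun with ``resume=True`` regenerates only stages whose outputs are
missing.
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np

from . import synthetic
from .compress import RandomProjectionCompressor
from .containers import FeatureMatrix
from .features import enumerate_pairs, exponential_contacts, pairwise_distances
from .io import read_json, read_table, write_json, write_table
from .msm import assign_states, cluster_summary, estimate_msm
from .tica import TICA

__all__ = ["RunConfig", "run_pipeline", "load_config"]

STAGES = ("synth", "featurize", "compress", "tica", "msm")

_DEFAULTS = {
    "run": {"seed": 0, "outdir": "run_out", "resume": False},
    "synth": {"preset": "two-state", "n_steps": 20000, "n_features": 50,
              "noise": 0.25, "n_residues": 39, "timestep_ns": 1.0},
    "compress": {"n": 10, "mode": "multi_net", "depth_min": 5,
                 "depth_max": 20, "width_min": 2, "width_max": 0,
                 "bias_lo": -1.0, "bias_hi": 1.0, "elu_alpha": 1.0},
    "tica": {"lag": 10, "epsilon": 1e-6, "k": 2},
    "msm": {"n_states": 2, "lag": 10,
            "lag_list": "", "q_boundaries": ""},
}


class RunConfig(dict):
    """Validated nested {section: {key: value}} run configuration."""

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = {sec: dict(defaults) for sec, defaults in _DEFAULTS.items()}
        for sec, items in raw.items():
            if sec not in cfg:
                raise ValueError(f"unknown config section [{sec}]")
            for key, value in items.items():
                if key not in cfg[sec]:
                    raise ValueError(f"unknown key {key!r} in section [{sec}]")
                default = cfg[sec][key]
                if isinstance(default, bool):
                    value = str(value).lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    value = int(value)
                elif isinstance(default, float):
                    value = float(value)
                cfg[sec][key] = value
        return cls(cfg)


def load_config(path) -> RunConfig:
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    return RunConfig.from_dict(
        {sec: dict(parser[sec]) for sec in parser.sections()})


def _stage_seeds(master: int) -> dict:
    seq = np.random.SeedSequence(master)
    children = seq.spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2 ** 31))
            for stage, c in zip(STAGES, children)}


def run_pipeline(config, outdir=None) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    The manifest maps each stage to its output files and child seed.  With
    ``run.resume`` true, stages whose outputs already exist are skipped and
    only downstream stages are regenerated.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    out = Path(outdir if outdir is not None else config["run"]["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config["run"]["seed"])
    resume = config["run"]["resume"]
    manifest_path = out / "manifest.json"
    manifest = {"seed": config["run"]["seed"], "stages": {}}

    def record(stage, files):
        manifest["stages"][stage] = {
            "seed": seeds[stage],
            "files": [str(Path(f).name) for f in files],
        }
        write_json(manifest_path, manifest)

    # once any stage recomputes, everything downstream recomputes too
    dirty = [False]

    def fresh(files):
        if resume and not dirty[0] and all(Path(f).exists() for f in files):
            return False
        dirty[0] = True
        return True

    try:
        # ---- synth -------------------------------------------------------
        scfg = config["synth"]
        traj_path = out / "trajectory.tsv"
        truth_path = out / "truth.json"
        states_path = out / "hidden_states.tsv"
        synth_files = [traj_path, truth_path, states_path]
        if scfg["preset"] == "toy-protein":
            synth_files.append(out / "toy_coords.npz")
        if fresh(synth_files):
            rng = np.random.default_rng(seeds["synth"])
            preset = scfg["preset"]
            if preset == "two-state":
                model = synthetic.two_state_model(
                    step_time_ns=scfg["timestep_ns"])
            elif preset == "four-state":
                model = synthetic.four_state_model(
                    step_time_ns=scfg["timestep_ns"])
            elif preset == "toy-protein":
                model = synthetic.two_state_model(
                    step_time_ns=scfg["timestep_ns"])
            else:
                raise ValueError(f"unknown preset {preset!r}")
            states = synthetic.simulate_chain(model, scfg["n_steps"], rng)
            if preset == "toy-protein":
                frames, reference, top = synthetic.make_toy_protein(
                    scfg["n_residues"], states, rng,
                    n_states=model.n_states)
                np.savez(out / "toy_coords.npz", frames=frames,
                         reference=reference)
                traj = FeatureMatrix(
                    frames.reshape(len(frames), -1),
                    timestep_ns=scfg["timestep_ns"])
            else:
                spec = synthetic.EmbeddingSpec(
                    n_features=scfg["n_features"],
                    noise_sd=scfg["noise"], jitter_sd=scfg["noise"])
                traj = synthetic.embed(states, spec, rng,
                                       scfg["timestep_ns"])
            write_table(traj_path, traj)
            write_table(states_path, FeatureMatrix(
                states[:, None].astype(float), ["state"],
                scfg["timestep_ns"]))
            write_json(truth_path, {
                "preset": preset,
                "transition_matrix": model.transition_matrix,
                "analytic_timescales_ns": model.timescales(),
                "stationary_distribution": model.stationary_distribution,
            })
        record("synth", synth_files)

        # ---- featurize ---------------------------------------------------
        feat_path = out / "features.tsv"
        if fresh([feat_path]):
            if scfg["preset"] == "toy-protein":
                with np.load(out / "toy_coords.npz") as data:
                    frames = data["frames"]
                top = synthetic.toy_protein_topology(scfg["n_residues"])
                pairs = enumerate_pairs(top, "calpha", 0)
                dists = pairwise_distances(frames, pairs,
                                           scfg["timestep_ns"])
                feats = exponential_contacts(dists, d0=1.0)
            else:
                feats = read_table(traj_path)
            write_table(feat_path, feats)
        record("featurize", [feat_path])

        # ---- compress ----------------------------------------------------
        ccfg = config["compress"]
        comp_path = out / "compressed.tsv"
        if fresh([comp_path]):
            feats = read_table(feat_path)
            width_max = ccfg["width_max"] or None
            comp = RandomProjectionCompressor(
                n_components=ccfg["n"], mode=ccfg["mode"].replace("-", "_"),
                depth_range=(ccfg["depth_min"], ccfg["depth_max"]),
                width_range=(ccfg["width_min"], width_max),
                bias_range=(ccfg["bias_lo"], ccfg["bias_hi"]),
                elu_alpha=ccfg["elu_alpha"],
                random_state=seeds["compress"])
            Z = comp.fit_transform(feats.values)
            write_table(comp_path, FeatureMatrix(
                Z, [f"g{i}" for i in range(ccfg["n"])], feats.timestep_ns,
                {"functions": comp.function_meta_}))
        record("compress", [comp_path])

        # ---- tica --------------------------------------------------------
        tcfg = config["tica"]
        eig_path = out / "tica_eigenvalues.tsv"
        proj_path = out / "tica_projection.tsv"
        if fresh([eig_path, proj_path]):
            Z = read_table(comp_path)
            tica = TICA(lag=tcfg["lag"], epsilon=tcfg["epsilon"]).fit(Z)
            k = min(tcfg["k"], tica.model_.rank)
            write_table(eig_path, FeatureMatrix(
                tica.eigenvalues_[None, :],
                [f"lambda{i + 1}" for i in range(len(tica.eigenvalues_))],
                Z.timestep_ns))
            write_table(proj_path, FeatureMatrix(
                tica.transform(Z)[:, :k],
                [f"tic{i + 1}" for i in range(k)], Z.timestep_ns))
        record("tica", [eig_path, proj_path])

        # ---- msm ---------------------------------------------------------
        mcfg = config["msm"]
        assign_path = out / "assignment.tsv"
        summary_path = out / "msm_summary.json"
        if fresh([assign_path, summary_path]):
            proj = read_table(proj_path)
            labels = assign_states(proj.values, mcfg["n_states"],
                                   seed=seeds["msm"])
            msm = estimate_msm(labels, mcfg["lag"], mcfg["n_states"],
                               proj.timestep_ns)
            summary = cluster_summary(labels)
            result = {
                "lag_frames": mcfg["lag"],
                "transition_matrix": msm.transition_matrix_,
                "eigenvalues": msm.eigenvalues_,
                "implied_timescales_ns": msm.timescales(),
                "populations": summary.populations,
            }
            lag_list = str(mcfg["lag_list"]).strip()
            if lag_list:
                lags = [int(x) for x in lag_list.split(",")]
                from .msm import timescales_vs_lag
                table = timescales_vs_lag(labels, lags, mcfg["n_states"],
                                          proj.timestep_ns)
                result["timescales_vs_lag"] = {
                    "lag_frames": table["lag_frames"].tolist(),
                    "process": table["process"].tolist(),
                    "timescale_ns": table["timescale_ns"].tolist(),
                }
            write_table(assign_path, FeatureMatrix(
                labels[:, None].astype(float), ["state"], proj.timestep_ns))
            write_json(summary_path, result)
        record("msm", [assign_path, summary_path])
    except Exception as exc:
        stage = STAGES[len(manifest["stages"])] if len(
            manifest["stages"]) < len(STAGES) else "unknown"
        write_json(manifest_path, manifest)
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}") from exc

    return manifest
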