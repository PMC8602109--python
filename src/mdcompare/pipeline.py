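"""Config-driven orchestration of the full comparative analysis.

A :class:`StudyConfig` (plain YAML) describes a synthetic multi-state,
multi-replica study — system size, per-state planted dynamics, analysis
windows and stage parameters — and :func:`run_pipeline` executes the
stages in dependency order, writing CSV/JSON reports plus a run manifest.
Every stage output is a pure function of (config, seed).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import kmeans_rmsd, populations, representative_frame
from .dcc import compute_dcc, tanimoto_similarity
from .ed import compute_ed, mode_similarity, variance_fractions, variance_total
from .model import Ensemble, concatenate
from .paths import build_graph, suboptimal_paths
from .pertnet import dynamical_contact_network, perturbation
from .site import (
    orientation_occupancy,
    overlap_fraction,
    pair_distance_stats,
    site_rmsd_distribution,
)
from .synthetic import (
    GaussianEnsembleSpec,
    linear_structure,
    make_gaussian_ensemble,
    residue_mode,
    spec_from_covariance,
)
from .model import SelectionSpec
from .trajectory import average_structure, replica_average, rmsd_series, rmsf_profile

__all__ = ["StudyConfig", "ConfigError", "Pipeline", "run_pipeline", "demo_config_path"]

STAGE_ORDER = ["rmsd", "rmsf", "ed", "dcc", "dpn", "wisp", "cluster", "site"]


class ConfigError(ValueError):
    """Raised when the study config fails validation."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def demo_config_path() -> Path:
    """Bundled demo config exercising every stage on synthetic data."""
    return Path(__file__).parent / "data" / "demo_config.yaml"


@dataclass
class StudyConfig:
    """Validated study description; see ``data/demo_config.yaml``."""

    raw: dict
    seed: int
    output_dir: Path
    system: dict
    states: dict
    n_replicas: int
    n_frames: int
    analysis_fraction: float
    reference_fraction: float
    stages: dict = field(default_factory=dict)

    @staticmethod
    def from_file(path, seed: int | None = None, output_dir=None) -> "StudyConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return StudyConfig.from_dict(raw, seed=seed, output_dir=output_dir)

    @staticmethod
    def from_dict(raw: dict, seed: int | None = None, output_dir=None) -> "StudyConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        try:
            system = dict(raw["system"])
            states = dict(raw["states"])
        except KeyError as exc:
            raise ConfigError(f"missing config section: {exc}") from exc
        if not states:
            raise ConfigError("at least one state must be defined")
        n_res = int(system.get("n_residues", 20))
        if n_res < 4:
            raise ConfigError("n_residues must be >= 4")
        cfg = StudyConfig(
            raw=raw,
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            output_dir=Path(output_dir or raw.get("output_dir", "mdcompare_out")),
            system=system,
            states=states,
            n_replicas=int(raw.get("n_replicas", 3)),
            n_frames=int(raw.get("n_frames", 200)),
            analysis_fraction=float(raw.get("analysis_window", 0.5)),
            reference_fraction=float(raw.get("reference_window", 0.2)),
            stages=dict(raw.get("stages", {})),
        )
        if cfg.n_replicas < 1 or cfg.n_frames < 10:
            raise ConfigError("need >= 1 replica and >= 10 frames")
        if not 0 < cfg.analysis_fraction <= 1 or not 0 < cfg.reference_fraction <= 1:
            raise ConfigError("window fractions must lie in (0, 1]")
        for name, sdef in cfg.states.items():
            if not isinstance(sdef, dict):
                raise ConfigError(f"state {name!r} must be a mapping")
        ref_state = cfg.stages.get("reference_state")
        if ref_state is not None and ref_state not in cfg.states:
            raise ConfigError(f"unknown reference_state {ref_state!r}")
        return cfg

    @property
    def reference_state(self) -> str:
        return self.stages.get("reference_state", list(self.states)[-1])


def _state_spec(cfg: StudyConfig, state_def: dict) -> GaussianEnsembleSpec:
    """Assemble the Gaussian spec of one state from its config block."""
    structure, ref = linear_structure(
        n_residues=int(cfg.system.get("n_residues", 20)),
        atoms_per_residue=int(cfg.system.get("atoms_per_residue", 4)),
        spacing=float(cfg.system.get("spacing", 4.0)),
        chain_split=cfg.system.get("chain_split"),
    )
    block = state_def.get("displaced_block")
    if block:
        disp = np.asarray(state_def.get("displacement", [0.0, 0.0, 0.0]), float)
        for r in block:
            ref[structure.residue_atoms(int(r))] += disp
    dim = 3 * structure.n_atoms
    cov = np.zeros((dim, dim))
    for mode in state_def.get("modes", []):
        directions = {
            int(r): np.asarray(mode.get("direction", [0, 1, 0]), float)
            for r in mode["residues"]
        }
        v = residue_mode(structure, directions, atoms=mode.get("atoms", "all"))
        cov += float(mode.get("amplitude", 1.0)) * np.outer(v, v)
    chain = state_def.get("chain")
    if chain:
        from .synthetic import _rep_atoms

        members = [int(r) for r in chain["residues"]]
        corr = float(chain.get("corr", 0.9))
        amp = float(chain.get("amplitude", 1.0))
        axis = int(chain.get("axis", 1))
        pos = np.arange(len(members), dtype=float)
        K = amp * corr ** ((pos[:, None] - pos[None, :]) ** 2)
        reps = _rep_atoms(structure)
        flat = [3 * reps[r] + axis for r in members]
        for a, ia in enumerate(flat):
            for b, ib in enumerate(flat):
                cov[ia, ib] += K[a, b]
    noise = float(state_def.get("noise_sigma", 0.1))
    return spec_from_covariance(structure, ref, cov, noise_sigma=noise)


def _mixture_ensemble(cfg: StudyConfig, mdef: dict, seed: int):
    """Discrete-conformer state: base geometry with a block displaced."""
    from .synthetic import ConformerMixtureSpec, make_conformer_mixture

    structure, ref = linear_structure(
        n_residues=int(cfg.system.get("n_residues", 20)),
        atoms_per_residue=int(cfg.system.get("atoms_per_residue", 4)),
        spacing=float(cfg.system.get("spacing", 4.0)),
        chain_split=cfg.system.get("chain_split"),
    )
    block = [int(r) for r in mdef.get("block", [])]
    conformers = []
    for disp in mdef["displacements"]:
        conf = ref.copy()
        d = np.asarray(disp, float)
        for r in block:
            conf[structure.residue_atoms(r)] += d
        conformers.append(conf)
    spec = ConformerMixtureSpec(
        structure=structure,
        conformers=tuple(conformers),
        weights=tuple(float(w) for w in mdef["weights"]),
        jitter_sigma=float(mdef.get("jitter_sigma", 0.1)),
    )
    return make_conformer_mixture(spec, cfg.n_frames, seed)


def _child_seed(base: int, state_index: int, replica: int) -> int:
    ss = np.random.SeedSequence([base, state_index, replica])
    return int(ss.generate_state(1)[0])


class Pipeline:
    """Stage runner with cached intermediates."""

    def __init__(self, config: StudyConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self._ensembles: dict[str, list[Ensemble]] | None = None
        self._reference: np.ndarray | None = None
        self.manifest: dict = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.seed,
            "parameters": config.raw,
            "stages_run": [],
        }

    # -- shared intermediates -------------------------------------------
    @property
    def ensembles(self) -> dict[str, list[Ensemble]]:
        if self._ensembles is None:
            cfg = self.config
            out: dict[str, list[Ensemble]] = {}
            for si, (name, sdef) in enumerate(cfg.states.items()):
                reps = []
                for ri in range(cfg.n_replicas):
                    seed = _child_seed(cfg.seed, si, ri)
                    if "mixture" in sdef:
                        ens, _ = _mixture_ensemble(cfg, sdef["mixture"], seed)
                        ens.replica_id = ri
                        ens.state_label = name
                    else:
                        ens = make_gaussian_ensemble(
                            _state_spec(cfg, sdef), cfg.n_frames,
                            seed=seed, replica_id=ri, state_label=name,
                        )
                    reps.append(ens)
                out[name] = reps
            self._ensembles = out
        return self._ensembles

    @property
    def reference(self) -> np.ndarray:
        """Average structure of the reference state's trailing window."""
        if self._reference is None:
            cfg = self.config
            reps = self.ensembles[cfg.reference_state]
            pooled = concatenate(
                [r.last_fraction(cfg.reference_fraction) for r in reps]
            )
            self._reference = average_structure(pooled, selection=self._fit_sel())
        return self._reference

    def _fit_sel(self) -> str:
        return self.config.stages.get("fit_selection", "ca")

    def _analysis_sel(self) -> str:
        return self.config.stages.get("analysis_selection", "backbone")

    def _window(self, ensemble: Ensemble) -> Ensemble:
        return ensemble.last_fraction(self.config.analysis_fraction)

    # -- stages ----------------------------------------------------------
    def run_stage(self, name: str) -> None:
        fn = getattr(self, f"stage_{name}", None)
        if fn is None:
            raise ConfigError(f"unknown stage {name!r}")
        self.outdir.mkdir(parents=True, exist_ok=True)
        try:
            fn()
        except Exception as exc:  # halt dependents, report stage and cause
            raise StageError(name, exc) from exc
        self.manifest["stages_run"].append(name)

    def stage_rmsd(self) -> None:
        rows = []
        for state, reps in self.ensembles.items():
            means = []
            for rep in reps:
                series = rmsd_series(
                    self._window(rep), self.reference,
                    selection=self._analysis_sel(),
                    reference_name=f"{self.config.reference_state}-average",
                )
                means.append(series.mean)
                rows.append({
                    "state": state, "replica": rep.replica_id,
                    "mean": round(series.mean, 4), "sd": round(series.sd, 4),
                })
            rows.append({
                "state": state, "replica": "average",
                "mean": replica_average(means), "sd": "",
            })
        pd.DataFrame(rows).to_csv(self.outdir / "rmsd_table.csv", index=False)

    def stage_rmsf(self) -> None:
        frames = []
        cfg = self.config
        n = self.ensembles[list(cfg.states)[0]][0].n_frames
        start = n - max(1, int(round(n * cfg.analysis_fraction)))
        for state, reps in self.ensembles.items():
            prof = rmsf_profile(reps, selection=self._analysis_sel(), start=start)
            frames.append(pd.DataFrame({
                "state": state,
                "residue": prof.residue_indices,
                "mean": np.round(prof.mean, 4),
                "sd": np.round(prof.sd, 4),
            }))
        pd.concat(frames).to_csv(self.outdir / "rmsf_profile.csv", index=False)

    def stage_ed(self) -> None:
        cfg = self.config
        k = int(cfg.stages.get("ed_modes", 4))
        table = []
        sims = []
        self._ed_results: dict[str, list] = {}
        for state, reps in self.ensembles.items():
            eds = [
                compute_ed(self._window(r), selection=self._analysis_sel())
                for r in reps
            ]
            self._ed_results[state] = eds
            for rep, ed in zip(reps, eds):
                fracs, total = variance_fractions(ed, k)
                fr = [round(float(x), 1) for x in fracs]
                table.append({
                    "state": state, "replica": rep.replica_id,
                    **{f"proj{i + 1}": v for i, v in enumerate(fr)},
                    "total": variance_total(fr),
                })
            for a in range(len(eds)):
                for b in range(a + 1, len(eds)):
                    sims.append({
                        "state": state, "replica_a": a, "replica_b": b,
                        "rmsip_k1": round(mode_similarity(eds[a], eds[b], 1), 4),
                        "rmsip_k3": round(mode_similarity(eds[a], eds[b], 3), 4),
                    })
        pd.DataFrame(table).to_csv(self.outdir / "ed_contributions.csv", index=False)
        pd.DataFrame(sims).to_csv(self.outdir / "ed_similarity.csv", index=False)

    def stage_dcc(self) -> None:
        sims = []
        self._dcc: dict = {}
        for state, reps in self.ensembles.items():
            mats = [compute_dcc(self._window(r), selection="ca") for r in reps]
            self._dcc[state] = mats
            mats[0].write_csv(self.outdir / f"dcc_{state}_rep0.csv")
            for a in range(len(mats)):
                for b in range(a + 1, len(mats)):
                    sims.append({
                        "state": state, "replica_a": a, "replica_b": b,
                        "tanimoto": round(tanimoto_similarity(mats[a], mats[b]), 4),
                    })
        pd.DataFrame(sims).to_csv(self.outdir / "dcc_tanimoto.csv", index=False)

    def _contact_net(self, state: str):
        cfg = self.config
        reps = [self._window(r) for r in self.ensembles[state]]
        return dynamical_contact_network(
            reps,
            cutoff=float(cfg.stages.get("contact_cutoff", 5.0)),
            exclude_bonded=int(cfg.stages.get("exclude_bonded", 1)),
        )

    def stage_dpn(self) -> None:
        cfg = self.config
        pair = cfg.stages.get("dpn_pair") or list(cfg.states)[:2]
        if len(pair) != 2 or any(p not in cfg.states for p in pair):
            raise ConfigError(f"dpn_pair must name two defined states, got {pair}")
        net_a = self._contact_net(pair[0])
        net_b = self._contact_net(pair[1])
        dpn = perturbation(
            net_a, net_b, threshold=float(cfg.stages.get("dpn_threshold", 5.0))
        )
        structure = self.ensembles[pair[0]][0].structure
        dpn.write_csv(self.outdir / "dpn_edges.csv")
        dpn.write_graphml(self.outdir / "dpn.graphml", structure)

    def stage_wisp(self) -> None:
        cfg = self.config
        wcfg = cfg.stages.get("wisp", {})
        state = wcfg.get("state", list(cfg.states)[0])
        pooled = concatenate([self._window(r) for r in self.ensembles[state]])
        dcc = compute_dcc(pooled, selection="ca")
        mask = None
        if wcfg.get("masked", False):
            mask = self._contact_net(state)
        structure = pooled.structure
        graph = build_graph(
            dcc, structure, pooled.coords[0], mask=mask,
            mask_min_weight=float(wcfg.get("mask_min_weight", 1.0)),
        )
        source = int(wcfg.get("source", 0))
        sink = int(wcfg.get("sink", structure.n_residues - 1))
        pset = suboptimal_paths(
            graph, source, sink,
            mode=wcfg.get("mode", "within_delta"),
            k_or_delta=float(wcfg.get("k_or_delta", 1.0)),
        )
        pset.to_dataframe(structure).to_csv(
            self.outdir / "wisp_paths.tsv", sep="\t", index=False
        )
        with open(self.outdir / "wisp_paths.json", "w") as fh:
            json.dump({
                "state": state, "source": source, "sink": sink,
                "paths": pset.to_records(),
            }, fh, indent=2)

    def stage_cluster(self) -> None:
        cfg = self.config
        ccfg = cfg.stages.get("cluster", {})
        state = ccfg.get("state", list(cfg.states)[0])
        pooled = concatenate([self._window(r) for r in self.ensembles[state]])
        result = kmeans_rmsd(
            pooled,
            selection=self._analysis_sel(),
            k=int(ccfg.get("k", 4)),
            sieve=int(ccfg.get("sieve", 10)),
            seed=cfg.seed,
        )
        pd.DataFrame({
            "frame": np.arange(result.n_frames), "cluster": result.labels,
        }).to_csv(self.outdir / "cluster_labels.csv", index=False)
        pops = populations(result)
        with open(self.outdir / "cluster_summary.json", "w") as fh:
            json.dump({
                "state": state, "k": result.k, "sieve": result.sieve,
                "populations": [
                    {"cluster": c, "percent": round(p, 4),
                     "representative_frame": representative_frame(result, c)}
                    for c, p in pops
                ],
            }, fh, indent=2)

    def stage_site(self) -> None:
        cfg = self.config
        scfg = cfg.stages.get("site", {})
        site_residues = tuple(int(r) for r in scfg.get("residues", [0, 1, 2]))
        site_sel = SelectionSpec(residues=site_residues, atom_class="backbone")
        report: dict = {"site_residues": list(site_residues), "states": {}}
        for state, reps in self.ensembles.items():
            pooled = concatenate([self._window(r) for r in reps])
            dist = site_rmsd_distribution(
                pooled, self.reference, site_sel, fit_selection=self._fit_sel(),
                reference_name=f"{cfg.reference_state}-average",
            )
            cutoff = scfg.get("overlap_cutoff")
            frac, used = overlap_fraction(
                dist, None if cutoff is None else float(cutoff)
            )
            report["states"][state] = {
                "peaks": [round(float(p), 3) for p in dist.peaks],
                "overlap_fraction": round(frac, 4),
                "overlap_cutoff": round(used, 3),
            }
        pair = scfg.get("distance_pair")
        if pair:
            state = pair.get("state", list(cfg.states)[0])
            pooled = concatenate([self._window(r) for r in self.ensembles[state]])
            stats = pair_distance_stats(
                pooled,
                SelectionSpec(residues=(int(pair["group_a"]),), atom_class="heavy"),
                SelectionSpec(residues=(int(pair["group_b"]),), atom_class="heavy"),
                contact_cutoff=float(pair.get("contact_cutoff", 4.0)),
            )
            report["distance_pair"] = {
                "state": state, "mean": round(stats.mean, 3),
                "sd": round(stats.sd, 3), "occupancy": round(stats.occupancy, 4),
            }
        ocfg = scfg.get("orientation")
        if ocfg:
            state = ocfg.get("state", list(cfg.states)[0])
            pooled = concatenate([self._window(r) for r in self.ensembles[state]])
            split = orientation_occupancy(
                pooled,
                SelectionSpec(residues=(int(ocfg["switch"]),), atom_class="heavy"),
                SelectionSpec(residues=(int(ocfg["partner_a"]),), atom_class="heavy"),
                SelectionSpec(residues=(int(ocfg["partner_b"]),), atom_class="heavy"),
                contact_cutoff=float(ocfg.get("contact_cutoff", 6.0)),
            )
            fa, fb = split.fractions()
            report["orientation"] = {
                "state": state, "percent_a": round(fa, 2),
                "percent_b": round(fb, 2),
                "percent_neither": round(split.neither_fraction, 2),
            }
        with open(self.outdir / "site_analysis.json", "w") as fh:
            json.dump(report, fh, indent=2)

    # -- driver ----------------------------------------------------------
    def run_all(self) -> Path:
        for stage in STAGE_ORDER:
            self.run_stage(stage)
        manifest_path = self.outdir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return self.outdir


def run_pipeline(config: StudyConfig) -> Path:
    """Execute every stage; returns the output directory."""
    return Pipeline(config).run_all()
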