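"""End-to-end orchestration: simulate → QC → classify → rates → RMSF (→ SAW).

One seeded, config-driven run producing a machine-readable report that
regenerates byte-identically under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from smfret import classify as _classify
from smfret import distance as _distance
from smfret import kinetics as _kinetics
from smfret import qc as _qc
from smfret import saw as _saw
from smfret import simulate as _simulate

logger = logging.getLogger("smfret.pipeline")

_SEED_NAMES = ("simulate", "classify", "kinetics", "jackknife", "saw")


@dataclass
class RunConfig:
    """All parameters of one pipeline run.

    ``label`` is free-text condition metadata (e.g. brush composition and
    temperature). When ``trajectory_file`` is set the simulation stage is
    skipped and trajectories are read from disk instead.
    """

    label: str = ""
    seed: int = 0
    n_trajectories: int = 1500
    trajectory_file: Optional[str] = None
    sidecar_file: Optional[str] = None
    transitions: _simulate.TransitionModel = field(default_factory=_simulate.TransitionModel)
    emission: _simulate.EmissionModel = field(default_factory=_simulate.EmissionModel)
    contaminants: _simulate.ContaminantSpec = field(default_factory=_simulate.ContaminantSpec)
    acquisition: _simulate.AcquisitionSettings = field(default_factory=_simulate.AcquisitionSettings)
    qc_min_frames: int = 4
    qc_intensity_cap_mad: float = 5.0
    classify_n_bins: int = 64
    classify_n_trials: int = 5
    kinetics_max_iter: int = 500
    kinetics_tol: float = 1e-6
    distance: _distance.DistanceModel = field(default_factory=_distance.DistanceModel)
    min_dwell: int = 3
    jackknife_blocks: int = 10
    saw: Optional[_saw.SawConfig] = None

    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: enc(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "transitions" in d and isinstance(d["transitions"], dict):
            d["transitions"] = _simulate.transition_model_from_dict(d["transitions"])
        if "emission" in d and isinstance(d["emission"], dict):
            d["emission"] = _simulate.emission_model_from_dict(d["emission"])
        if "contaminants" in d and isinstance(d["contaminants"], dict):
            d["contaminants"] = _simulate.contaminants_from_dict(d["contaminants"])
        if "acquisition" in d and isinstance(d["acquisition"], dict):
            d["acquisition"] = _simulate.acquisition_from_dict(d["acquisition"])
        if "distance" in d and isinstance(d["distance"], dict):
            d["distance"] = _distance.DistanceModel(**d["distance"])
        if d.get("saw") is not None and isinstance(d["saw"], dict):
            d["saw"] = _saw.SawConfig(**d["saw"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def child_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_SEED_NAMES))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_SEED_NAMES, children)
        }


@dataclass
class RunReport:
    """Machine-readable result bundle of one pipeline run."""

    payload: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def report_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.payload, sort_keys=True).encode()
        ).hexdigest()

    def __getitem__(self, key):
        return self.payload[key]


def run_pipeline(
    config: RunConfig,
    out_dir=None,
    make_figures: bool = False,
) -> RunReport:
    """Execute the full analysis chain described by ``config``.

    Mandatory stages (simulate/load, QC, classification, kinetics) abort
    the run on failure; optional stages (RMSF, SAW) degrade gracefully
    and mark their report section with the error instead.
    """
    seeds = config.child_seeds()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- data ----------------------------------------------------------
    if config.trajectory_file:
        logger.info("loading trajectories from %s", config.trajectory_file)
        tset = _simulate.TrajectorySet.read_tsv(
            config.trajectory_file, sidecar_path=config.sidecar_file,
            acq=config.acquisition,
        )
    else:
        logger.info("simulating %d trajectories", config.n_trajectories)
        tset = _simulate.generate_dataset(
            config.n_trajectories,
            transitions=config.transitions,
            emission=config.emission,
            contaminants=config.contaminants,
            acq=config.acquisition,
            rng_seed=seeds["simulate"],
        )
        if out is not None:
            tset.to_tsv(out / "trajectories.tsv", sidecar_path=out / "ground_truth.tsv")

    # -- QC ------------------------------------------------------------
    qc_result = _qc.run_qc(
        tset,
        min_frames=config.qc_min_frames,
        intensity_cap_mad=config.qc_intensity_cap_mad,
    )
    logger.info("QC: retained %d / %d", qc_result.report.n_retained, qc_result.report.n_input)
    if qc_result.report.n_retained == 0:
        raise RuntimeError("qc stage retained no trajectories")
    retained = qc_result.retained
    if out is not None:
        qc_result.report.to_json(out / "qc_report.json")

    # -- classification ------------------------------------------------
    cls_model = _classify.ThresholdClassificationModel(retained, n_bins=config.classify_n_bins)
    cls = cls_model.fit(n_trials=config.classify_n_trials, rng_seed=seeds["classify"])
    logger.info("phi_F = %.4f ± %.4f", cls.phi_f, cls.sd_trials)
    if out is not None:
        cls_model.heatmap.to_tsv(out / "heatmap.tsv")
        (out / "folded_fraction.json").write_text(
            json.dumps(cls.folded_fraction.to_dict(), indent=2, sort_keys=True) + "\n"
        )

    # -- kinetics --------------------------------------------------------
    init = _kinetics.init_from_classification(
        cls, background=config.emission.background, jitter_seed=seeds["kinetics"]
    )
    kin_model = _kinetics.KineticsModel(
        retained, init=init, background=config.emission.background
    )
    kin = kin_model.fit(max_iter=config.kinetics_max_iter, tol=config.kinetics_tol)
    logger.info(
        "k_fold = %.3f ± %.3f, k_unfold = %.3f ± %.3f s^-1",
        kin.k_fold, kin.rates.se_k_fold, kin.k_unfold, kin.rates.se_k_unfold,
    )

    # -- dwell fluctuations (optional) -----------------------------------
    rmsf_section: dict = {}
    try:
        decoded = kin.decoded_frame(retained)
        fluct = _distance.fluctuation_analysis(
            decoded,
            model=config.distance,
            min_dwell=config.min_dwell,
            n_blocks=config.jackknife_blocks,
            rng_seed=seeds["jackknife"],
        )
        rmsf_section = {state: res.to_dict() for state, res in fluct.items()}
        if out is not None:
            decoded.to_csv(out / "decoded.tsv", sep="\t", index=False, float_format="%.3f")
    except Exception as exc:  # noqa: BLE001 - optional stage degrades gracefully
        logger.warning("rmsf stage failed: %s", exc)
        rmsf_section = {"error": str(exc)}

    # -- SAW (optional) --------------------------------------------------
    saw_section = None
    if config.saw is not None:
        try:
            saw_cfg = dataclasses.replace(config.saw, rng_seed=seeds["saw"])
            saw_section = _saw.end_to_end_ensemble(saw_cfg).to_dict()
            logger.info("SAW mean distance %.2f nm", saw_section["mean_nm"])
        except Exception as exc:  # noqa: BLE001
            logger.warning("saw stage failed: %s", exc)
            saw_section = {"error": str(exc)}

    from smfret import __version__

    payload = {
        "label": config.label,
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "qc": qc_result.report.to_dict(),
        "folded_fraction": cls.folded_fraction.to_dict(),
        "phi_f_hmm_occupancy": kin.occupancy_folded_fraction(),
        "rates": kin.rates.to_dict(),
        "hmm": {
            "converged": kin.converged,
            "n_iterations": int(len(kin.loglik_path)),
            "loglik_per_frame": float(kin.loglik_path[-1]),
        },
        "rmsf": rmsf_section,
        "saw": saw_section,
    }
    report = RunReport(payload)

    if out is not None:
        report.to_json(out / "report.json")
        if make_figures:
            from smfret import plots

            plots.save_run_figures(out, cls, kin, rmsf_section)
    return report
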