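"""End-to-end orchestration: charge model → conformers → turns → aggregates.

One validated YAML config drives the whole analysis and produces one JSON
run report plus CSV tables, all reproducible from the seed recorded in the
report.  The stages mirror the study design for a pH-responsive
self-assembling peptide: establish the per-site charge state at every
requested pH, obtain a multi-chain ensemble (generated or loaded),
quantify turn/β-turn content, and characterize the aggregates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .aggregates import analyze_frame
from .charge import (
    BJELLQVIST,
    PKaSet,
    charge_state_model,
    isoelectric_point,
    NoIsoelectricPointError,
)
from .peptide import PeptideSpec
from .structio import read_gro, read_pdb, write_pdb
from .synth import make_system
from .turns import TurnCriteria, turn_content

logger = logging.getLogger("pepassembly")

__all__ = ["PipelineConfig", "GeneratorSpec", "run_pipeline", "load_config"]


class GeneratorSpec(BaseModel):
    """Synthetic-system recipe (the stand-in for a trajectory)."""

    n_chains: int = Field(ge=1)
    box_nm: float = Field(default=8.0, gt=0)
    placement: Literal["dispersed", "micellar"] = "dispersed"
    min_dist_A: float = Field(default=4.0, gt=0)
    seed: int  # mandatory: no wall-clock seeding
    motif: Optional[str] = None
    n_frames: int = Field(default=1, ge=1)


class TurnCriteriaConfig(BaseModel):
    ca_dist_max: float = Field(default=7.0, gt=0)
    hbond_ON_max: float = Field(default=3.5, gt=0)
    hbond_angle_min: float = Field(default=120.0, gt=0)
    combine: Literal["either", "both"] = "either"
    exclude_helix: bool = True

    def build(self) -> TurnCriteria:
        return TurnCriteria(**self.model_dump())


class PipelineConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    sequence: str
    n_term_free: bool = True
    c_term_free: bool = True
    ph_values: list[float] = Field(default=[2.0, 7.0, 8.0, 11.0])
    pka_set: Literal["bjellqvist"] = "bjellqvist"
    input_path: Optional[str] = None
    generator: Optional[GeneratorSpec] = None
    turn_criteria: TurnCriteriaConfig = Field(default_factory=TurnCriteriaConfig)
    cluster_cutoff_A: float = Field(default=4.5, gt=0)
    dielectric: float = Field(default=78.5, gt=0)
    coulomb_cutoff_nm: float = Field(default=1.4, gt=0)
    output_dir: str = "pepassembly_run"

    @model_validator(mode="after")
    def _one_input(self) -> "PipelineConfig":
        if (self.input_path is None) == (self.generator is None):
            raise ValueError(
                "config must provide exactly one of 'input_path' or 'generator'"
            )
        for ph in self.ph_values:
            if not 0.0 <= ph <= 14.0:
                raise ValueError(f"ph_values entry {ph} outside [0, 14]")
        PeptideSpec(self.sequence, self.n_term_free, self.c_term_free)
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _pka_set(config: PipelineConfig) -> PKaSet:
    return BJELLQVIST


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and write the run report.

    Stage order: charge → (generate | load) → turns → aggregates.  Any
    stage failure aborts the run, removes partial outputs, and re-raises
    with the stage named.  Returns the report dict (also written as
    ``report.json`` in the output directory).
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    peptide = PeptideSpec(config.sequence, config.n_term_free, config.c_term_free)
    pka = _pka_set(config)
    report: dict = {
        "software": {"name": "pepassembly", "version": __version__},
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "thresholds": {
            "turn_criteria": config.turn_criteria.model_dump(),
            "cluster_cutoff_A": config.cluster_cutoff_A,
            "dielectric": config.dielectric,
            "coulomb_cutoff_nm": config.coulomb_cutoff_nm,
            "pka_set": pka.name,
        },
    }

    stage = "charge"
    try:
        charge_rows = []
        charge_report = {}
        for ph in config.ph_values:
            cm = charge_state_model(peptide, ph, pka)
            charge_report[str(ph)] = {
                "net_charge": cm.net_charge,
                "rounded_net_charge": cm.rounded_net_charge,
                "sites": [
                    {
                        "kind": site.site_kind,
                        "residue": site.residue_index,
                        "pKa": site.pKa,
                        "charge": q,
                        "label": label,
                    }
                    for (site, q), label in zip(cm.site_charges, cm.site_labels)
                ],
            }
            charge_rows.append(
                {"pH": ph, "net_charge": cm.net_charge, "rounded": cm.rounded_net_charge}
            )
        report["charge"] = charge_report
        try:
            report["isoelectric_point"] = isoelectric_point(peptide, pka)
        except NoIsoelectricPointError:
            report["isoelectric_point"] = None
        df = pd.DataFrame(charge_rows)
        p = out / "charge.csv"
        df.to_csv(p, index=False)
        written.append(p)
        logger.info("stage=charge ph_values=%d sites=%d", len(config.ph_values),
                    len(charge_report[str(config.ph_values[0])]["sites"]))

        stage = "system"
        if config.generator is not None:
            g = config.generator
            system = make_system(
                peptide,
                n_chains=g.n_chains,
                box_nm=g.box_nm,
                placement=g.placement,
                min_dist_A=g.min_dist_A,
                seed=g.seed,
                per_chain_motif=g.motif,
                n_frames=g.n_frames,
            )
            p = out / "system.pdb"
            write_pdb(system, p)
            written.append(p)
            report["system"] = {"source": "generated", "seed": g.seed}
        else:
            path = Path(config.input_path)
            reader = read_gro if path.suffix.lower() == ".gro" else read_pdb
            system = reader(path, config.n_term_free, config.c_term_free)
            report["system"] = {"source": str(path)}
        report["system"].update(
            {"n_frames": system.n_frames, "n_chains": system.n_chains,
             "box_nm": system.box_nm}
        )
        logger.info("stage=system frames=%d chains=%d", system.n_frames, system.n_chains)

        stage = "turns"
        criteria = config.turn_criteria.build()
        tc = turn_content(system, criteria)
        report["turns"] = {
            "turn_percent": tc.turn_percent,
            "beta_turn_percent": tc.beta_turn_percent,
            "turn_percent_sd": tc.turn_percent_sd,
            "beta_turn_percent_sd": tc.beta_turn_percent_sd,
            "per_frame_turn": list(tc.per_frame_turn),
            "per_frame_beta_turn": list(tc.per_frame_beta_turn),
        }
        p = out / "turns.csv"
        pd.DataFrame(
            {
                "frame": range(system.n_frames),
                "turn_percent": tc.per_frame_turn,
                "beta_turn_percent": tc.per_frame_beta_turn,
            }
        ).to_csv(p, index=False)
        written.append(p)
        logger.info("stage=turns frames=%d turn=%.1f beta=%.1f",
                    system.n_frames, tc.turn_percent, tc.beta_turn_percent)

        stage = "aggregates"
        ph_for_scores = config.ph_values[0] if config.ph_values else None
        frame_reports = [
            analyze_frame(
                frame,
                cutoff_A=config.cluster_cutoff_A,
                pH=ph_for_scores,
                pka_set=pka,
                dielectric=config.dielectric,
                coulomb_cutoff_nm=config.coulomb_cutoff_nm,
            )
            for frame in system.frames
        ]
        report["aggregates"] = frame_reports
        logger.info("stage=aggregates frames=%d clusters_frame0=%d",
                    len(frame_reports),
                    len(frame_reports[0]["aggregates"]) if frame_reports else 0)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    p = out / "report.json"
    p.write_text(json.dumps(report, indent=2, default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
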