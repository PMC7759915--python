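"""End-to-end orchestration: CSV inputs -> analysis stages -> report bundle.

Each stage runs only when its input file is present; skipped stages are
logged.  The bundle is a directory of tidy CSVs plus one machine-readable
``report.json`` that records every parameter used (provenance map).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .assay import ColonyCountRecord, assay_summary, read_colony_csv
from .biodistribution import TissueBoronRecord, summarize, tumor_ratios
from .dosimetry import (
    BeamSpec,
    DoseComponents,
    DoseScenario,
    KermaSet,
    WeightSet,
    dose_report,
)
from .errors import ConfigurationError, InvalidInputError
from .radiobiology import (
    CBEResult,
    DoseSFPoint,
    LQParams,
    beam_rbe,
    compound_cbe,
    fit_lq,
)
from .survival import SurvivalRecord, survival_report
from .synthetic import (
    SyntheticConfig,
    boron_dose_rate_per_min,
    config_from_dict,
    nonboron_rates_per_min,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "photon_points_from_counts",
    "sf_time_points",
    "estimate_condition_cbe",
]

logger = logging.getLogger("bnctkit.pipeline")


# ---------------------------------------------------------------------------
# estimation helpers reused by tests and the acceptance script


def photon_points_from_counts(frame: pd.DataFrame) -> list[DoseSFPoint]:
    """Pooled (dose, SF) points from a per-dish photon colony table.

    The dose-0 rows define the control plating efficiency.  Doses whose
    estimated SF is 0 are dropped (not fittable on the log scale); estimates
    above 1 are clipped to 1.
    """
    required = {"dose_gy", "cells_seeded", "colonies"}
    if not required.issubset(frame.columns):
        raise InvalidInputError(f"photon table needs columns {sorted(required)}")
    pooled = frame.groupby("dose_gy", sort=True)[["cells_seeded", "colonies"]].sum()
    if 0.0 not in pooled.index:
        raise InvalidInputError("photon table needs dose 0 rows as the control")
    pe = pooled["colonies"] / pooled["cells_seeded"]
    pe0 = pe.loc[0.0]
    if pe0 == 0:
        raise InvalidInputError("control plating efficiency is zero")
    points = []
    for dose, value in pe.items():
        if dose == 0.0:
            continue
        sf = value / pe0
        if sf <= 0.0:
            continue
        points.append(DoseSFPoint(dose=float(dose), sf=min(float(sf), 1.0)))
    return points


def sf_time_points(
    records: Sequence[ColonyCountRecord], control_id: str = "control"
) -> dict[str, list[DoseSFPoint]]:
    """(irradiation time, SF) points per condition from colony records.

    SF estimates above 1 are clipped to 1 and zero estimates dropped, mirroring
    :func:`photon_points_from_counts`.
    """
    summary = assay_summary(records, control_id=control_id)
    out: dict[str, list[DoseSFPoint]] = {}
    for _, row in summary.iterrows():
        if row["condition_id"] == control_id:
            continue
        sf = float(row["survival_fraction"])
        if sf <= 0.0:
            continue
        out.setdefault(row["condition_id"], []).append(
            DoseSFPoint(
                dose=float(row["irradiation_min"]),
                sf=min(sf, 1.0),
                condition_id=str(row["condition_id"]),
            )
        )
    return out


def estimate_condition_cbe(
    photon_lq: LQParams,
    points: Sequence[DoseSFPoint],
    cellular_boron: float,
    beam: BeamSpec,
    kerma: KermaSet,
    weights: WeightSet,
    sf_level: float = 0.1,
) -> CBEResult:
    """CBE for one compound condition given its cellular boron concentration."""
    r_n, r_h, r_g = nonboron_rates_per_min(beam)
    return compound_cbe(
        photon_lq=photon_lq,
        compound_points=points,
        beam_rates=DoseComponents(0.0, r_n, r_h, r_g),
        boron_dose_rate=boron_dose_rate_per_min(cellular_boron, beam, kerma),
        weights=weights,
        sf_level=sf_level,
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Paths and reporting options for one pipeline run.

    Beam/kerma/weights and per-condition boron concentrations are read from
    ``manifest.json`` in the input directory (written by ``simulate``);
    sensible defaults are used when the manifest is absent.
    """

    input_dir: Path
    output_dir: Path
    control_condition: str = "control"
    control_group: str = "control"
    sf_level: float = 0.1
    detection_floor: float = 0.5
    contribution_fraction_ced: float = 0.25
    full_precision: bool = False
    holm: bool = False

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)

    @property
    def round_to(self) -> Optional[int]:
        return None if self.full_precision else 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle)
        if not isinstance(data, dict):
            raise ConfigurationError(f"run config {path!r} must be a mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "input_dir": str(self.input_dir),
            "output_dir": str(self.output_dir),
            "control_condition": self.control_condition,
            "control_group": self.control_group,
            "sf_level": self.sf_level,
            "detection_floor": self.detection_floor,
            "contribution_fraction_ced": self.contribution_fraction_ced,
            "full_precision": self.full_precision,
            "holm": self.holm,
        }


def _load_manifest(config: RunConfig) -> Optional[SyntheticConfig]:
    path = config.input_dir / "manifest.json"
    if not path.exists():
        return None
    with open(path) as handle:
        return config_from_dict(json.load(handle))


def _jsonable(value):
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, float):
        return None if math.isnan(value) else value
    return value


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage whose input exists; return (and write) the report bundle.

    Raises :class:`ConfigurationError` if no stage could run at all.
    """
    config.output_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(config)
    synth = manifest if manifest is not None else SyntheticConfig()
    report: dict = {
        "tool_version": __version__,
        "run_config": config.to_dict(),
        "stages_run": [],
        "stages_skipped": [],
        "provenance": {
            "beam": {
                "flux": synth.beam.flux,
                "duration_s": synth.beam.duration,
                "nonboron_dose_rate_gy_s": synth.beam.nonboron_dose_rate,
                "component_split": list(synth.beam.component_split),
            },
            "kerma": {"boron_coefficient": synth.kerma.boron_coefficient},
            "weights": {
                "rbe_n": synth.true_weights.rbe_n,
                "rbe_h": synth.true_weights.rbe_h,
                "cbe_brain": synth.true_weights.cbe_brain,
            },
            "manifest_found": manifest is not None,
            "sf_level": config.sf_level,
        },
    }

    colony_path = config.input_dir / "colony_assay.csv"
    photon_path = config.input_dir / "photon_assay.csv"
    biodist_path = config.input_dir / "biodistribution.csv"
    survival_path = config.input_dir / "survival.csv"

    # --- assay stage -------------------------------------------------------
    colony_records: Optional[list[ColonyCountRecord]] = None
    if colony_path.exists():
        colony_records = read_colony_csv(colony_path)
        summary = assay_summary(colony_records, control_id=config.control_condition)
        summary.to_csv(config.output_dir / "assay_summary.csv", index=False)
        report["stages_run"].append("assay")
        report["assay"] = {
            "n_conditions": int(summary["condition_id"].nunique()),
            "control_plating_efficiency": float(
                summary.loc[
                    summary["condition_id"] == config.control_condition,
                    "plating_efficiency",
                ].iloc[0]
            ),
        }
    else:
        logger.info("assay stage skipped: %s not found", colony_path)
        report["stages_skipped"].append("assay")

    # --- radiobiology stage ------------------------------------------------
    photon_lq: Optional[LQParams] = None
    fitted_cbe: dict[str, float] = {}
    if photon_path.exists():
        photon_points = photon_points_from_counts(pd.read_csv(photon_path))
        photon_lq = fit_lq(photon_points)
        report["stages_run"].append("lq_fit")
        report["lq_photon"] = {
            "alpha": photon_lq.alpha,
            "beta": photon_lq.beta,
            "n_points": len(photon_points),
            "at_boundary": photon_lq.at_boundary,
        }
    else:
        logger.info("LQ stage skipped: %s not found", photon_path)
        report["stages_skipped"].append("lq_fit")

    if photon_lq is not None and colony_records is not None:
        condition_points = sf_time_points(colony_records, config.control_condition)
        rbe_cbe: dict = {}
        conditions = {c.condition_id: c for c in synth.assay_conditions}
        for condition_id, points in condition_points.items():
            spec = conditions.get(condition_id)
            if spec is not None and spec.cellular_boron == 0.0:
                # boron-free arm: beam RBE via physical beam dose vs SF
                rate = synth.beam.nonboron_dose_rate * 60.0  # Gy/min
                beam_points = [
                    DoseSFPoint(dose=p.dose * rate, sf=p.sf, condition_id=condition_id)
                    for p in points
                ]
                iso = beam_rbe(photon_lq, beam_points, sf_level=config.sf_level)
                rbe_cbe[condition_id] = {
                    "kind": "beam_rbe",
                    "rbe": iso.rbe,
                    "photon_iso_dose_gy": iso.reference_dose,
                    "beam_iso_dose_gy": iso.comparison_dose,
                }
            elif spec is not None:
                result = estimate_condition_cbe(
                    photon_lq,
                    points,
                    spec.cellular_boron,
                    synth.beam,
                    synth.kerma,
                    synth.true_weights,
                    sf_level=config.sf_level,
                )
                fitted_cbe.setdefault(spec.compound or condition_id, result.cbe)
                rbe_cbe[condition_id] = {
                    "kind": "cbe",
                    "compound": spec.compound,
                    "cbe": result.cbe,
                    "iso_effect_time_min": result.iso_effect_time,
                    "physical_dose_gy": result.physical_dose,
                    "cellular_boron_ug_g": spec.cellular_boron,
                }
            else:
                logger.warning(
                    "condition %r has no manifest entry; CBE not estimated", condition_id
                )
        if rbe_cbe:
            report["stages_run"].append("rbe_cbe")
            report["rbe_cbe"] = rbe_cbe
            with open(config.output_dir / "rbe_cbe.json", "w") as handle:
                json.dump(_jsonable(rbe_cbe), handle, indent=2, sort_keys=True)
                handle.write("\n")

    # --- biodistribution stage ---------------------------------------------
    biodist_summary: Optional[pd.DataFrame] = None
    if biodist_path.exists():
        frame = pd.read_csv(biodist_path)
        records = [
            TissueBoronRecord(
                animal_id=str(row["animal_id"]),
                compound=str(row["compound"]),
                route=str(row["route"]),
                dose=float(row["dose_mg_b_kg"]),
                time_h=float(row["time_h"]),
                tissue=str(row["tissue"]),
                concentration=float(row["concentration_ug_b_g"]),
            )
            for _, row in frame.iterrows()
        ]
        biodist_summary = summarize(records, detection_floor=config.detection_floor)
        biodist_summary.to_csv(config.output_dir / "biodist_summary.csv", index=False)

        ratio_rows = []
        wide = biodist_summary.pivot_table(
            index=["compound", "route", "time_h"], columns="tissue", values="mean"
        )
        for key, row in wide.iterrows():
            if not {"tumor", "brain", "blood"}.issubset(row.dropna().index):
                continue
            t_br, t_bl = tumor_ratios(
                row["tumor"], row["brain"], row["blood"], round_to=config.round_to
            )
            ratio_rows.append(
                {
                    "compound": key[0],
                    "route": key[1],
                    "time_h": key[2],
                    "tumor_to_brain": t_br,
                    "tumor_to_blood": t_bl,
                }
            )
        ratios = pd.DataFrame(ratio_rows)
        ratios.to_csv(config.output_dir / "biodist_ratios.csv", index=False)
        report["stages_run"].append("biodistribution")
        report["biodistribution"] = {
            "n_groups": int(len(biodist_summary)),
            "ratios": ratios.to_dict(orient="records"),
            "detection_floor_ug_b_g": config.detection_floor,
        }
    else:
        logger.info("biodistribution stage skipped: %s not found", biodist_path)
        report["stages_skipped"].append("biodistribution")

    # --- dosimetry stage -----------------------------------------------------
    # Needs tumor boron summaries and per-compound CBE values (fitted upstream
    # when available, otherwise the configured truth).
    if biodist_summary is not None:
        scenarios = []
        weight_map: dict[Optional[str], WeightSet] = {}
        base = synth.true_weights
        for _, row in biodist_summary.iterrows():
            if row["tissue"] not in ("tumor", "brain"):
                continue
            compound = row["compound"]
            cbe = fitted_cbe.get(compound, base.cbe)
            weight_map[compound] = WeightSet(
                cbe=cbe, rbe_n=base.rbe_n, rbe_h=base.rbe_h, cbe_brain=base.cbe_brain
            )
            scenarios.append(
                DoseScenario(
                    tissue=f"{row['tissue']} ({compound} {row['route']} {row['time_h']:g}h)",
                    boron_mean=float(row["mean"]),
                    boron_sd=float(row["sd"]),
                    contribution_fraction=(
                        config.contribution_fraction_ced if row["route"] == "ced" else 1.0
                    ),
                    compound=compound,
                    use_brain_cbe=row["tissue"] == "brain",
                )
            )
        table = dose_report(
            scenarios, synth.beam, synth.kerma, weight_map, round_to=config.round_to
        )
        table.to_csv(config.output_dir / "dose_report.csv", index=False)
        report["stages_run"].append("dosimetry")
        report["dosimetry"] = {
            "n_rows": int(len(table)),
            "cbe_by_compound": {str(k): v.cbe for k, v in weight_map.items()},
            "contribution_fraction_ced": config.contribution_fraction_ced,
        }
    else:
        report["stages_skipped"].append("dosimetry")

    # --- survival stage ------------------------------------------------------
    if survival_path.exists():
        frame = pd.read_csv(survival_path)
        records = [
            SurvivalRecord(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                time=float(row["time_days"]),
                event=int(row["event"]),
            )
            for _, row in frame.iterrows()
        ]
        summary, p_matrix = survival_report(
            records,
            control_group=config.control_group,
            holm=config.holm,
            round_to=config.round_to,
        )
        summary.to_csv(config.output_dir / "survival_summary.csv", index=False)
        p_matrix.to_csv(config.output_dir / "logrank_matrix.csv")
        report["stages_run"].append("survival")
        report["survival"] = {
            "groups": summary.to_dict(orient="records"),
            "control_group": config.control_group,
        }
    else:
        logger.info("survival stage skipped: %s not found", survival_path)
        report["stages_skipped"].append("survival")

    if not report["stages_run"]:
        raise ConfigurationError(
            f"no stage input found under {config.input_dir}; nothing to do"
        )

    with open(config.output_dir / "report.json", "w") as handle:
        json.dump(_jsonable(report), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return report
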