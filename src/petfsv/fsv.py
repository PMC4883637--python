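"""Forward stroke volume by the indicator-dilution equation.

FSV = I / (AUC x HR), with I the injected dose (Bq), AUC the first-pass
area under the blood curve (Bq*s/mL) and HR the heart rate converted to
beats per second; the quotient is in mL per beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .clustering import (
    BloodPoolSegmentation,
    ClusterConfig,
    extract_cluster_tac,
    segment_blood_pools,
)
from .firstpass import FirstPassConfig, FirstPassCurve, isolate_first_pass
from .io import AcquisitionContext, DynamicSeries, TimeActivityCurve


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class FSVResult:
    fsv_arterial_ml: float
    fsv_venous_ml: float
    fsv_average_ml: float
    auc_arterial: float  # Bq*s/mL
    auc_venous: float  # Bq*s/mL
    context: AcquisitionContext
    anchors: Dict[str, Tuple[int, int]]  # (t1, t2) frame indices per pool

    def __post_init__(self) -> None:
        if min(self.fsv_arterial_ml, self.fsv_venous_ml, self.fsv_average_ml) <= 0:
            raise ValueError("FSV values must be positive")

    def to_dict(self) -> dict:
        return {
            "fsv_arterial_ml": self.fsv_arterial_ml,
            "fsv_venous_ml": self.fsv_venous_ml,
            "fsv_average_ml": self.fsv_average_ml,
            "auc_arterial_Bq_s_per_mL": self.auc_arterial,
            "auc_venous_Bq_s_per_mL": self.auc_venous,
            "dose_MBq": self.context.injected_dose_mbq,
            "hr_per_min": self.context.heart_rate_per_min,
            "anchors": {k: list(v) for k, v in self.anchors.items()},
        }


@dataclass(frozen=True)
class PipelineOutputs:
    """Full audit trail of an image-to-FSV run."""

    result: FSVResult
    segmentation: BloodPoolSegmentation
    arterial_tac: TimeActivityCurve
    venous_tac: TimeActivityCurve
    arterial_first_pass: FirstPassCurve
    venous_first_pass: FirstPassCurve


def compute_fsv(dose_bq: float, auc: float, heart_rate_per_min: float) -> float:
    """Indicator-dilution stroke volume in mL.

    Units: Bq / (Bq*s/mL x beats/s) = mL per beat.
    """
    if dose_bq <= 0:
        raise ValueError("dose must be positive")
    if auc <= 0:
        raise ValueError("AUC must be positive")
    if heart_rate_per_min <= 0:
        raise ValueError("heart rate must be positive")
    return dose_bq / (auc * heart_rate_per_min / 60.0)


def run_pipeline(
    series: DynamicSeries,
    context: AcquisitionContext,
    cluster_config: Optional[ClusterConfig] = None,
    first_pass_config: Optional[FirstPassConfig] = None,
    selection_mode: str = "auto",
    manual_ids: Optional[Tuple[int, int]] = None,
) -> PipelineOutputs:
    """Clustering -> selection -> erosion -> TAC -> first pass -> FSV."""
    try:
        seg = segment_blood_pools(series, cluster_config, selection_mode, manual_ids)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("blood_pool_segmentation", exc) from exc

    tacs: Dict[str, TimeActivityCurve] = {}
    fps: Dict[str, FirstPassCurve] = {}
    fsvs: Dict[str, float] = {}
    for pool, mask in (
        ("arterial", seg.eroded_arterial_mask),
        ("venous", seg.eroded_venous_mask),
    ):
        try:
            tacs[pool] = extract_cluster_tac(series, mask)
        except Exception as exc:
            raise PipelineError(f"{pool}_tac_extraction", exc) from exc
        try:
            fps[pool] = isolate_first_pass(tacs[pool], first_pass_config)
        except Exception as exc:
            raise PipelineError(f"{pool}_first_pass_isolation", exc) from exc
        fsvs[pool] = compute_fsv(
            context.injected_dose_bq, fps[pool].auc, context.heart_rate_per_min
        )

    result = FSVResult(
        fsv_arterial_ml=fsvs["arterial"],
        fsv_venous_ml=fsvs["venous"],
        fsv_average_ml=(fsvs["arterial"] + fsvs["venous"]) / 2.0,
        auc_arterial=fps["arterial"].auc,
        auc_venous=fps["venous"].auc,
        context=context,
        anchors={
            pool: (fps[pool].t1_index, fps[pool].t2_index) for pool in ("arterial", "venous")
        },
    )
    return PipelineOutputs(
        result=result,
        segmentation=seg,
        arterial_tac=tacs["arterial"],
        venous_tac=tacs["venous"],
        arterial_first_pass=fps["arterial"],
        venous_first_pass=fps["venous"],
    )


def compute_fsv_report(
    series: DynamicSeries,
    context: AcquisitionContext,
    cluster_config: Optional[ClusterConfig] = None,
    first_pass_config: Optional[FirstPassConfig] = None,
    selection_mode: str = "auto",
    manual_ids: Optional[Tuple[int, int]] = None,
) -> FSVResult:
    """Image-to-FSV pipeline returning only the result record."""
    return run_pipeline(
        series, context, cluster_config, first_pass_config, selection_mode, manual_ids
    ).result
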