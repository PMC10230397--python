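"""Cohort-level metric computation from cleaned scan records.

Ties the per-pair operations together for a whole cohort: choose a reference
scan per patient (planning, or a designated treatment scan for the
sensitivity re-analysis), rigidly align every other scan to it, crop to the
common field of view, and compute gas, body-contour, anterior-surface and
SGRT correction metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .icp import ICPParams
from .metrics import (
    AnteriorWindow,
    anterior_surface_map,
    body_separation,
    gas_metrics,
    gas_volume,
    surface_separation,
)
from .register import align_scan, common_fov_crop, register_masks_rigid
from .sgrt import sgrt_correction
from .volume import PLANNING, ScanRecord, sort_scans


@dataclass(frozen=True)
class MetricParams:
    window: AnteriorWindow = field(default_factory=AnteriorWindow)
    icp: ICPParams = field(default_factory=ICPParams)
    include_planning: bool = True
    #: patient id -> reference timepoint; None = planning scan everywhere
    reference: dict | None = None


def compute_patient_metrics(
    scans: list[ScanRecord],
    params: MetricParams | None = None,
    isocenter_mm=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metrics for one patient's scan set.

    Returns (fraction_rows, summary_row) as DataFrames. The isocenter for the
    SGRT decomposition defaults to the reference-scan body centroid (no plan
    files exist for synthetic cohorts).
    """
    params = params or MetricParams()
    scans = sort_scans(scans)
    pid = scans[0].patient_id
    ref_tp = PLANNING if params.reference is None else params.reference[pid]
    by_tp = {s.timepoint: s for s in scans}
    if ref_tp not in by_tp:
        raise ValueError(f"patient {pid}: reference timepoint {ref_tp} missing")
    ref = by_tp[ref_tp]
    if isocenter_mm is None:
        isocenter_mm = ref.body.centroid_mm()

    volumes = {tp: gas_volume(s.gas) for tp, s in by_tp.items()}
    gm = gas_metrics(
        volumes, include_planning=params.include_planning, reference=ref_tp
    )

    rows = []
    for scan in scans:
        tp = scan.timepoint
        if tp == ref_tp or tp not in gm.volumes_ml:
            continue
        offset = register_masks_rigid(ref.body, scan.body, params.icp)
        aligned, extent = align_scan(scan, offset, reference=ref.body)
        ref_c, mov_c = common_fov_crop(ref, aligned, moving_extent_mm=extent)
        body_sep = body_separation(ref_c, mov_c)
        ref_map = anterior_surface_map(ref_c.body, params.window)
        mov_map = anterior_surface_map(mov_c.body, params.window)
        surf_sep = surface_separation(ref_map, mov_map)
        correction, icp_res = sgrt_correction(
            ref_c, mov_c, isocenter_mm, params.icp, params.window
        )
        rows.append(
            dict(
                patient_id=pid, timepoint=tp,
                gas_ml=volumes[tp], gas_rel_ml=gm.gas_rel_ml[tp],
                body_avg_signed_mm=body_sep.mean_signed,
                body_avg_unsigned_mm=body_sep.mean_unsigned,
                surface_avg_signed_mm=surf_sep.mean_signed,
                surface_avg_unsigned_mm=surf_sep.mean_unsigned,
                t_x=correction.t_x, t_y=correction.t_y, t_z=correction.t_z,
                r_x=correction.r_x, r_y=correction.r_y, r_z=correction.r_z,
                setup_t_x=offset.t_x, setup_t_y=offset.t_y, setup_t_z=offset.t_z,
                setup_r_x=offset.r_x, setup_r_y=offset.r_y, setup_r_z=offset.r_z,
                sgrt_residual_mm=icp_res.residual_mm,
            )
        )
    fractions = pd.DataFrame(rows)
    summary = pd.DataFrame(
        [
            dict(
                patient_id=pid,
                reference=ref_tp,
                gas_std_ml=gm.gas_std_ml,
                body_avg_unsigned_mm=fractions["body_avg_unsigned_mm"].mean(),
                surface_avg_unsigned_mm=fractions["surface_avg_unsigned_mm"].mean(),
            )
        ]
    )
    return fractions, summary


def compute_cohort_metrics(
    scans_by_patient: dict[str, list[ScanRecord]],
    params: MetricParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fraction and per-patient metric tables for a whole cohort."""
    params = params or MetricParams()
    fractions = []
    summaries = []
    for pid in sorted(scans_by_patient):
        if params.reference is not None and pid not in params.reference:
            continue
        frac, summ = compute_patient_metrics(scans_by_patient[pid], params)
        fractions.append(frac)
        summaries.append(summ)
    if not fractions:
        raise ValueError("no patients with computable metrics")
    return (
        pd.concat(fractions, ignore_index=True),
        pd.concat(summaries, ignore_index=True),
    )
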