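"""Adaptive semi-automatic protocol and the end-to-end pipeline driver.

The recommended protocol starts at the 15%max threshold and tries
neighbouring cutoffs (lower: 10, 5; higher: 20, 25, 30) while an
objective improves — a scripted, auditable surrogate for the expert's
visual adaptation.  Two objectives are provided: ``match_reference``
(distance to a reference contour's %WL volume, the evaluation setting)
and ``plateau`` (flattest local volume response to the cutoff, a
reference-free surrogate for operator judgement).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import BinaryMask, CaseRecord, ImageVolume
from .delineate import DEFAULT_CUTOFFS, MaxEstimate, ThresholdSweep, delineate_at, estimate_max, sweep
from .evaluate import CaseEvaluation, CohortSummary, evaluate_case, summarize_cohort
from .io import write_volume
from .lungseg import LungSegParams, segment_lungs
from .phantom import PhantomCase, cohort_table

logger = logging.getLogger("vqfv")

DEFAULT_ADAPTIVE_CUTOFFS: tuple[float, ...] = (5, 10, 15, 20, 25, 30)
START_CUTOFF = 15.0


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and case."""


@dataclass
class AdaptiveResult:
    chosen_cutoff: float
    trajectory: list[tuple[float, float]]  # (cutoff, objective value), in walk order
    objective: str
    final_mask: BinaryMask
    final_volume_pct_wl: float


def adaptive_delineate(pet: ImageVolume, wl: BinaryMask, max_est: MaxEstimate,
                       objective: str = "plateau",
                       reference: Optional[BinaryMask] = None,
                       candidate_cutoffs: Sequence[float] = DEFAULT_ADAPTIVE_CUTOFFS) -> AdaptiveResult:
    """Greedy neighbour-walk over the candidate cutoffs, starting at 15%max.

    The walk moves to an adjacent candidate while the objective strictly
    improves, so the trajectory is contiguous and the result never
    scores worse than the starting threshold.
    """
    cands = sorted(float(c) for c in candidate_cutoffs)
    if not cands:
        raise ValueError("empty candidate cutoff list")
    if START_CUTOFF not in cands:
        raise ValueError(f"candidate cutoffs must include {START_CUTOFF}")
    if objective == "match_reference" and reference is None:
        raise ValueError("match_reference objective requires a reference mask")

    vols = {c: delineate_at(pet, wl, max_est, c)[1] for c in cands}

    if objective == "match_reference":
        ref_pct = 100.0 * reference.voxel_count / wl.voxel_count

        def score(c: float) -> float:
            return abs(vols[c] - ref_pct)
    elif objective == "plateau":
        def score(c: float) -> float:
            i = cands.index(c)
            slopes = []
            for j in (i - 1, i + 1):
                if 0 <= j < len(cands):
                    slopes.append(abs(vols[cands[j]] - vols[c]) / abs(cands[j] - c))
            return float(np.mean(slopes)) if slopes else 0.0
    else:
        raise ValueError(f"unknown objective {objective!r}")

    cur = START_CUTOFF
    trajectory = [(cur, score(cur))]
    while True:
        i = cands.index(cur)
        neighbours = [cands[j] for j in (i - 1, i + 1) if 0 <= j < len(cands)]
        if not neighbours:
            break
        nxt = min(neighbours, key=score)
        if score(nxt) < trajectory[-1][1]:
            cur = nxt
            trajectory.append((cur, score(cur)))
        else:
            break
    mask, vol = delineate_at(pet, wl, max_est, cur)
    return AdaptiveResult(chosen_cutoff=cur, trajectory=trajectory, objective=objective,
                          final_mask=mask, final_volume_pct_wl=vol)


@dataclass
class PipelineConfig:
    """Everything :func:`run_case` needs, in one place."""

    lungseg: LungSegParams = field(default_factory=LungSegParams)
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    max_policy: str = "auto"
    peak_ratio: float = 1.5
    max_hot_ml: float = 5.0
    exclusion_margin_mm: float = 8.0
    report_cutoff: float = 15.0
    write_masks: bool = False

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        seg = LungSegParams(**cfg.pop("lungseg", {}))
        cutoffs = tuple(cfg.pop("cutoffs", DEFAULT_CUTOFFS))
        return cls(lungseg=seg, cutoffs=cutoffs, **cfg)


@dataclass
class ModalityResult:
    max_estimate: MaxEstimate
    sweep: ThresholdSweep
    evaluations: Optional[list[CaseEvaluation]] = None


@dataclass
class CaseResult:
    case_id: str
    wl: BinaryMask
    results: dict[str, ModalityResult]  # keyed "vent" / "perf"


def run_case(case: CaseRecord, config: Optional[PipelineConfig] = None,
             references: Optional[Mapping[str, BinaryMask]] = None,
             out_dir: Optional[Path] = None) -> CaseResult:
    """WL segmentation -> max estimation -> sweep -> optional evaluation.

    ``references`` maps ``"vent"``/``"perf"`` to reference contours
    (e.g. phantom ground truth).  Deterministic given config and inputs;
    any stage failure raises :class:`StageError` naming the stage.
    """
    config = config or PipelineConfig()
    cid = case.case_id
    try:
        wl = segment_lungs(case.ct, config.lungseg)
    except Exception as e:
        raise StageError(f"segment_lungs | {cid} | {e}") from e
    logger.info("segment_lungs | %s | WL %.0f ml", cid, wl.volume_ml)

    pets = {k: v for k, v in (("vent", case.pet_vent), ("perf", case.pet_perf)) if v is not None}
    if not pets:
        raise StageError(f"delineate | {cid} | case has no PET volumes")

    results: dict[str, ModalityResult] = {}
    for key, pet in pets.items():
        try:
            mx = estimate_max(pet, wl, policy=config.max_policy,
                              peak_ratio=config.peak_ratio, max_hot_ml=config.max_hot_ml,
                              exclusion_margin_mm=config.exclusion_margin_mm)
            sw = sweep(pet, wl, mx, config.cutoffs)
        except Exception as e:
            raise StageError(f"delineate | {cid} | {key} | {e}") from e
        evals = None
        ref = (references or {}).get(key)
        if ref is not None:
            try:
                evals = evaluate_case(sw, ref, wl, case_id=cid)
            except Exception as e:
                raise StageError(f"evaluate | {cid} | {key} | {e}") from e
        results[key] = ModalityResult(max_estimate=mx, sweep=sw, evaluations=evals)
        logger.info("delineate | %s | %s | max %.1f (excl %d vox)", cid, key,
                    mx.value, mx.diagnostics.get("n_excluded_voxels", 0))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(wl, out_dir / "wl.nii.gz")
        for key, res in results.items():
            res.sweep.to_frame().to_csv(out_dir / f"{key}_sweep.csv", index=False,
                                        float_format="%.6f")
            if config.write_masks:
                for c, m in zip(res.sweep.cutoffs_pct, res.sweep.masks):
                    write_volume(m, out_dir / f"{key}_func_{c:g}pct.nii.gz")
            if res.evaluations is not None:
                pd.DataFrame([vars(e) for e in res.evaluations]).to_csv(
                    out_dir / f"{key}_case_eval.csv", index=False, float_format="%.6f")
    return CaseResult(case_id=cid, wl=wl, results=results)


def run_phantom_cohort(cases: Sequence[PhantomCase],
                       config: Optional[PipelineConfig] = None
                       ) -> tuple[dict[str, dict[str, list[CaseEvaluation]]], pd.DataFrame, list[CaseResult]]:
    """Run the pipeline over phantom cases, evaluating against their truth.

    Returns per-modality per-case evaluations, a per-case table
    (true fractions, PFTs, %WL per cutoff), and the raw case results.
    Failed cases are logged and skipped so a cohort run completes.
    """
    config = config or PipelineConfig()
    evals: dict[str, dict[str, list[CaseEvaluation]]] = {"vent": {}, "perf": {}}
    case_results = []
    rows = []
    for pc in cases:
        refs = {}
        if pc.truth_functional_vent is not None:
            refs["vent"] = pc.truth_functional_vent
        if pc.truth_functional_perf is not None:
            refs["perf"] = pc.truth_functional_perf
        try:
            cr = run_case(pc.case, config, references=refs)
        except StageError as e:
            logger.error("cohort | %s | case failed: %s", pc.case.case_id, e)
            continue
        case_results.append(cr)
        row = {"case_id": cr.case_id,
               "true_fraction_vent": pc.true_fraction_vent,
               "true_fraction_perf": pc.true_fraction_perf}
        row.update(pc.case.pft or {})
        for key, res in cr.results.items():
            if res.evaluations is not None:
                evals[key][cr.case_id] = res.evaluations
            for c, v in zip(res.sweep.cutoffs_pct, res.sweep.volumes_pct_wl):
                row[f"{key}_pct_wl_{c:g}"] = v
        rows.append(row)
    table = pd.DataFrame(rows).set_index("case_id") if rows else pd.DataFrame()
    evals = {k: v for k, v in evals.items() if v}
    return evals, table, case_results


def summarize_phantom_cohort(cases: Sequence[PhantomCase],
                             config: Optional[PipelineConfig] = None,
                             report_cutoff: float = 15.0
                             ) -> tuple[dict[str, CohortSummary], pd.DataFrame]:
    """Cohort summaries per modality, evaluated against phantom truth."""
    config = config or PipelineConfig()
    evals, table, _ = run_phantom_cohort(cases, config)
    pft = cohort_table(cases)[[c for c in cohort_table(cases).columns
                               if c not in ("true_fraction_vent", "true_fraction_perf")]]
    pft = pft if not pft.empty and pft.shape[1] else None
    summaries = {key: summarize_cohort(ev, pft_table=pft, report_cutoff=report_cutoff)
                 for key, ev in evals.items()}
    return summaries, table


MODALITY_TITLES = {"vent": "Ventilation", "perf": "Perfusion"}


def write_cohort_report(out_dir, summaries: Mapping[str, CohortSummary],
                        plots: bool = False) -> None:
    """Write table1.csv, table2.csv, bland_altman.csv (+ optional plots).

    ``table1.csv``: per-modality mean/SD/min/max volume-difference rows,
    one column per cutoff.  ``table2.csv``: one row per PFT index with
    r, p and p<0.05 flags for the automatic (report cutoff) and the
    reference volumes, per modality.  Output is deterministic, so
    re-running produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t1_rows = []
    for key, summ in summaries.items():
        pc = summ.per_cutoff
        for stat, col in (("Mean", "mean_diff"), ("Std deviation", "sd_diff"),
                          ("Minimum", "min_diff"), ("Maximum", "max_diff")):
            row = {"modality": MODALITY_TITLES.get(key, key), "statistic": stat}
            row.update({f"{c:g}%": pc.loc[c, col] for c in pc.index})
            t1_rows.append(row)
    pd.DataFrame(t1_rows).to_csv(out_dir / "table1.csv", index=False, float_format="%.6f")

    t2 = None
    for key, summ in summaries.items():
        if summ.pft_correlations is None:
            continue
        part = summ.pft_correlations.rename(columns={
            "auto_r": f"{key}_auto_r", "auto_p": f"{key}_auto_p",
            "auto_significant": f"{key}_auto_significant",
            "ref_r": f"{key}_ref_r", "ref_p": f"{key}_ref_p",
            "ref_significant": f"{key}_ref_significant"})
        t2 = part if t2 is None else t2.join(part)
    if t2 is not None:
        t2.to_csv(out_dir / "table2.csv", float_format="%.6f")

    ba_rows = []
    for key, summ in summaries.items():
        a = summ.agreement
        ba_rows.append({"modality": MODALITY_TITLES.get(key, key),
                        "report_cutoff": summ.report_cutoff, "bias": a.bias, "sd": a.sd,
                        "loa_low": a.loa_low, "loa_high": a.loa_high,
                        "diff_min": a.diff_min, "diff_max": a.diff_max, "n": a.n})
    pd.DataFrame(ba_rows).to_csv(out_dir / "bland_altman.csv", index=False, float_format="%.6f")

    if plots:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from .evaluate import bland_altman_plot  # noqa: F401 (kept for API users)
        for key, summ in summaries.items():
            fig, ax = plt.subplots(figsize=(5, 4))
            a = summ.agreement
            for y, style in ((a.bias, "-"), (a.loa_low, "--"), (a.loa_high, "--")):
                ax.axhline(y, linestyle=style, color="k", linewidth=1)
            ax.set_title(f"{MODALITY_TITLES.get(key, key)} — Bland-Altman "
                         f"(bias {a.bias:.1f}, LoA {a.loa_low:.1f}..{a.loa_high:.1f})")
            ax.set_xlabel("mean of automatic and reference (%WL)")
            ax.set_ylabel("difference (%WL points)")
            fig.savefig(out_dir / f"bland_altman_{key}.png", dpi=120)
            plt.close(fig)
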