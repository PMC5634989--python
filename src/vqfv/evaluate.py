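"""Agreement and correlation statistics for delineated volumes.

Per case: signed volume differences (%WL points) and Dice coefficients
against a reference contour, per cutoff.  Per cohort: mean/SD/min/max of
the volume difference, median/IQR of Dice, Pearson correlation of
automatic vs reference volumes, Bland-Altman agreement at a reporting
cutoff, and Pearson correlations with pulmonary-function indices.

Conventions: SD uses the n-1 denominator; limits of agreement are
bias +/- 1.96 SD; the Dice of two empty masks is 1.0 (identical masks,
logged); all computation is at full precision, rounding happens only at
presentation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask, assert_same_lattice
from .delineate import ThresholdSweep

logger = logging.getLogger("vqfv")

LOA_MULTIPLIER = 1.96
SIGNIFICANCE_LEVEL = 0.05


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``.

    Defined as 1.0 when both masks are empty (they are identical).
    """
    assert_same_lattice(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        logger.warning("evaluate | dice of two empty masks defined as 1.0")
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def volume_difference(auto_pct_wl: float, ref_pct_wl: float) -> float:
    """Signed difference automatic - reference, in %WL points."""
    return auto_pct_wl - ref_pct_wl


@dataclass
class AgreementStats:
    """Bland-Altman summary of paired differences (%WL points)."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    diff_min: float
    diff_max: float
    n: int


def bland_altman(diffs: Sequence[float]) -> AgreementStats:
    """Bland-Altman agreement: bias, SD (n-1), bias +/- 1.96 SD, extremes."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError(f"Bland-Altman needs >= 2 differences, got {d.size}")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(bias=bias, sd=sd,
                          loa_low=bias - LOA_MULTIPLIER * sd,
                          loa_high=bias + LOA_MULTIPLIER * sd,
                          diff_min=float(d.min()), diff_max=float(d.max()),
                          n=int(d.size))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CaseEvaluation:
    """Automatic-vs-reference comparison at one cutoff for one case."""

    case_id: str
    cutoff_pct: float
    volume_pct_wl_auto: float
    volume_pct_wl_ref: float
    volume_diff: float
    dsc: float


def evaluate_case(sw: ThresholdSweep, reference: BinaryMask, wl: BinaryMask,
                  case_id: str = "") -> list[CaseEvaluation]:
    """One :class:`CaseEvaluation` per cutoff of the sweep.

    The reference volume is expressed as %WL on the same WL mask used
    for delineation, so both terms share one denominator.
    """
    assert_same_lattice(reference, wl)
    n_wl = wl.voxel_count
    if n_wl == 0:
        raise ValueError("empty whole-lung mask")
    ref_pct = 100.0 * reference.voxel_count / n_wl
    out = []
    for c, m, v in zip(sw.cutoffs_pct, sw.masks, sw.volumes_pct_wl):
        out.append(CaseEvaluation(case_id=case_id, cutoff_pct=c,
                                  volume_pct_wl_auto=v, volume_pct_wl_ref=ref_pct,
                                  volume_diff=volume_difference(v, ref_pct),
                                  dsc=dice(m, reference)))
    return out


def _best_cutoff(cutoffs: Sequence[float], scores: Sequence[float],
                 anchor: float = 15.0) -> float:
    """Cutoff minimising the score; ties go to the cutoff nearest the
    anchor (the recommended starting threshold), then to the lower one."""
    best = min(zip(scores, cutoffs), key=lambda t: (t[0], abs(t[1] - anchor), t[1]))
    return best[1]


def best_cutoff_per_case(evals: Sequence[CaseEvaluation]) -> float:
    """Cutoff minimising |volume difference| for one case."""
    if not evals:
        raise ValueError("no evaluations")
    return _best_cutoff([e.cutoff_pct for e in evals],
                        [abs(e.volume_diff) for e in evals])


@dataclass
class CohortSummary:
    """Cohort-level aggregation across cases and cutoffs."""

    per_cutoff: pd.DataFrame          # indexed by cutoff_pct
    best_cutoff_overall: float
    best_cutoff_histogram: dict[float, int]
    agreement: AgreementStats         # Bland-Altman at report_cutoff
    report_cutoff: float
    pft_correlations: Optional[pd.DataFrame]
    n: int


def summarize_cohort(case_evals: Mapping[str, Sequence[CaseEvaluation]],
                     pft_table: Optional[pd.DataFrame] = None,
                     report_cutoff: float = 15.0) -> CohortSummary:
    """Aggregate per-case evaluations into cohort tables.

    ``per_cutoff`` rows carry mean/SD/min/max of the volume difference,
    median and IQR of Dice, and the Pearson r between automatic and
    reference %WL volumes.  ``pft_table`` (indexed by case_id, columns =
    PFT indices) adds correlations of each index with the automatic %WL
    at ``report_cutoff`` and with the reference %WL; cases missing an
    index are dropped pairwise with a logged count.
    """
    if len(case_evals) < 2:
        raise ValueError("cohort summary needs >= 2 cases")
    records = [e for evs in case_evals.values() for e in evs]
    df = pd.DataFrame([vars(e) for e in records])

    rows = []
    for c, grp in df.groupby("cutoff_pct"):
        rows.append({
            "cutoff_pct": c,
            "mean_diff": grp.volume_diff.mean(),
            "sd_diff": grp.volume_diff.std(ddof=1),
            "min_diff": grp.volume_diff.min(),
            "max_diff": grp.volume_diff.max(),
            "dsc_median": grp.dsc.median(),
            "dsc_iqr_low": grp.dsc.quantile(0.25),
            "dsc_iqr_high": grp.dsc.quantile(0.75),
            "pearson_r": pearson(grp.volume_pct_wl_auto, grp.volume_pct_wl_ref)[0]
            if grp.volume_pct_wl_auto.nunique() > 1 and grp.volume_pct_wl_ref.nunique() > 1
            else float("nan"),
        })
    per_cutoff = pd.DataFrame(rows).set_index("cutoff_pct").sort_index()

    best_overall = _best_cutoff(per_cutoff.index.to_list(),
                                per_cutoff.mean_diff.abs().to_list())
    hist: dict[float, int] = {c: 0 for c in per_cutoff.index}
    for cid, evs in case_evals.items():
        hist[best_cutoff_per_case(list(evs))] += 1

    at_rep = df[df.cutoff_pct == report_cutoff]
    if at_rep.empty:
        raise ValueError(f"report_cutoff {report_cutoff} not present in the evaluations")
    agreement = bland_altman(at_rep.volume_diff.to_numpy())

    pft_corr = None
    if pft_table is not None:
        auto = at_rep.set_index("case_id").volume_pct_wl_auto
        ref = at_rep.set_index("case_id").volume_pct_wl_ref
        rows = []
        for idx_name in pft_table.columns:
            y = pft_table[idx_name]
            common = auto.index.intersection(y.dropna().index)
            dropped = len(auto) - len(common)
            if dropped:
                logger.info("evaluate | %s | dropped %d cases without %s", idx_name, dropped, idx_name)
            r_a, p_a = pearson(auto.loc[common], y.loc[common])
            if ref.loc[common].nunique() > 1:
                r_r, p_r = pearson(ref.loc[common], y.loc[common])
            else:
                r_r, p_r = float("nan"), float("nan")
            rows.append({"pft_index": idx_name,
                         "auto_r": r_a, "auto_p": p_a,
                         "auto_significant": p_a < SIGNIFICANCE_LEVEL,
                         "ref_r": r_r, "ref_p": p_r,
                         "ref_significant": p_r < SIGNIFICANCE_LEVEL})
        pft_corr = pd.DataFrame(rows).set_index("pft_index")

    return CohortSummary(per_cutoff=per_cutoff, best_cutoff_overall=best_overall,
                         best_cutoff_histogram=hist, agreement=agreement,
                         report_cutoff=report_cutoff, pft_correlations=pft_corr,
                         n=len(case_evals))


def bland_altman_plot(auto: Sequence[float], ref: Sequence[float], ax=None,
                      title: str = ""):
    """Scatter of difference vs mean with bias and limits-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    auto = np.asarray(auto, dtype=float)
    ref = np.asarray(ref, dtype=float)
    diffs = auto - ref
    st = bland_altman(diffs)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((auto + ref) / 2.0, diffs, s=18)
    for y, style in ((st.bias, "-"), (st.loa_low, "--"), (st.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of automatic and reference (%WL)")
    ax.set_ylabel("automatic - reference (%WL points)")
    if title:
        ax.set_title(title)
    return ax
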