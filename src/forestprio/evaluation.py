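"""Resolution-error evaluation: spatial and conservation error vs the 16 m baseline.

A coarse-resolution priority solution is compared with the baseline solution
by (a) spatial error — the relative area its top fraction shares with the
baseline top fraction (overlap) and the complementary error of omission —
and (b) conservation error — the relative change in each feature's protected
total, where both solutions' protected totals are evaluated on the baseline
16 m data.  Negative conservation error means the coarse solution protects
less of the feature than the baseline solution does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureStack
from .ranking import BenefitConfig, PriorityRanking, rank_cells, top_fraction

TOP_FRACTIONS = (0.02, 0.10)


def footprint(mask: np.ndarray, resolution: float, base_resolution: float = 16.0) -> np.ndarray:
    """Expand a coarse selection mask to the baseline grid.

    Every selected coarse cell covers its (resolution/base)**2 constituent
    baseline cells.
    """
    ratio = resolution / base_resolution
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(f"resolution {resolution} is not a multiple of {base_resolution}")
    return np.kron(np.asarray(mask, dtype=bool), np.ones((k, k), dtype=bool))


def spatial_error(mask_base: np.ndarray, mask_coarse_fp: np.ndarray) -> tuple[float, float]:
    """(overlap, omission) of a coarse footprint against the baseline top fraction.

    overlap = |intersection| / |baseline mask|; omission = 1 - overlap.  Both
    masks must live on the baseline grid.
    """
    mask_base = np.asarray(mask_base, dtype=bool)
    mask_coarse_fp = np.asarray(mask_coarse_fp, dtype=bool)
    if mask_base.shape != mask_coarse_fp.shape:
        raise ValueError(f"mask shapes differ: {mask_base.shape} vs {mask_coarse_fp.shape}")
    n_base = mask_base.sum()
    if n_base == 0:
        raise ValueError("baseline mask is empty")
    overlap = float((mask_base & mask_coarse_fp).sum() / n_base)
    return overlap, 1.0 - overlap


def conservation_error(
    stack16: FeatureStack,
    mask_base: np.ndarray,
    mask_coarse_fp: np.ndarray,
) -> pd.DataFrame:
    """Per-feature relative change in protected totals, on baseline data.

    For each feature j, S_j(mask) sums the baseline-layer values inside the
    mask; the error is (S_j(coarse) - S_j(base)) / S_j(base).  Features whose
    baseline-protected total is zero are flagged ``defined=False`` (error
    reported as NaN) rather than propagated.
    """
    mask_base = np.asarray(mask_base, dtype=bool)
    mask_coarse_fp = np.asarray(mask_coarse_fp, dtype=bool)
    if mask_base.shape != stack16.shape or mask_coarse_fp.shape != stack16.shape:
        raise ValueError("masks must share the baseline stack's grid")
    rows = []
    for lyr in stack16:
        s_base = float(lyr.values[mask_base].sum())
        s_fp = float(lyr.values[mask_coarse_fp].sum())
        defined = s_base > 0
        err = (s_fp - s_base) / s_base if defined else np.nan
        rows.append(
            {
                "feature": lyr.name,
                "variable": lyr.variable,
                "species": lyr.species,
                "site_class": lyr.site_class,
                "protected_base": s_base,
                "protected_coarse": s_fp,
                "conservation_error": err,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExperimentResult:
    """Everything one six-resolution run produces."""

    seed: int
    rankings: dict[float, PriorityRanking]
    spatial: pd.DataFrame  # (resolution_m, top_fraction, overlap, omission)
    conservation: pd.DataFrame  # per (resolution_m, top_fraction, feature)
    curves: dict[float, pd.DataFrame] = field(default_factory=dict)


def evaluate_pyramid(
    pyramid: dict[float, FeatureStack],
    config: BenefitConfig = BenefitConfig(),
    top_fractions: tuple[float, ...] = TOP_FRACTIONS,
    tie_rule: str = "lexicographic",
    seed: int | None = None,
    base_resolution: float | None = None,
) -> ExperimentResult:
    """Rank every resolution independently and compare against the baseline.

    The finest resolution in the pyramid is the baseline.  For every coarser
    resolution and top fraction, the coarse solution's footprint on the
    baseline grid is scored for spatial error and, on the baseline data, for
    per-feature conservation error.  The baseline rows (overlap 1, omission
    0, zero conservation error) are included.
    """
    resolutions = sorted(pyramid)
    base_res = base_resolution if base_resolution is not None else resolutions[0]
    stack16 = pyramid[base_res]
    rankings = {
        res: rank_cells(pyramid[res], config=config, tie_rule=tie_rule, seed=seed)
        for res in resolutions
    }
    spatial_rows = []
    cons_frames = []
    for res in resolutions:
        for p in top_fractions:
            mask_coarse = top_fraction(rankings[res], p)
            fp = footprint(mask_coarse, res, base_res)
            mask_base = top_fraction(rankings[base_res], p)
            overlap, omission = spatial_error(mask_base, fp)
            spatial_rows.append(
                {
                    "resolution_m": res,
                    "top_fraction": p,
                    "overlap": overlap,
                    "omission": omission,
                    "footprint_cells": int(fp.sum()),
                    "baseline_cells": int(mask_base.sum()),
                }
            )
            cons = conservation_error(stack16, mask_base, fp)
            cons.insert(0, "resolution_m", res)
            cons.insert(1, "top_fraction", p)
            cons_frames.append(cons)
    return ExperimentResult(
        seed=-1 if seed is None else int(seed),
        rankings=rankings,
        spatial=pd.DataFrame(spatial_rows),
        conservation=pd.concat(cons_frames, ignore_index=True),
    )
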