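"""Median-shift normalization of per-gene profiles within experiment blocks.

Expression values from different "reference-less" experiments (single-channel
intensities, global-reference two-colour ratios) have no common zero point,
so profiles are only comparable across experiments after each gene's values
within each experiment are centred.  Median-shift normalization subtracts
each gene's within-experiment median, e.g. a gene measured at (11, 4, 6)
across one experiment's three conditions becomes (5, −2, 0).

The median of an even number of values is the midpoint of the two central
order statistics; a single observed value normalizes to 0; missing values
are ignored when computing the median and stay missing afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ExprMapError
from .io_formats import ExpressionMatrix


@dataclass
class NormalizationPlan:
    """Which experiment blocks to median-shift.

    ``experiments_to_shift = None`` means all experiments (the default);
    pass an explicit set to shift only reference-less experiments and leave
    absolutely-calibrated ones untouched.
    """

    experiments_to_shift: set[str] | None = None

    def resolve(self, matrix: ExpressionMatrix) -> set[str]:
        present = set(matrix.experiment_ids)
        if self.experiments_to_shift is None:
            return present
        unknown = set(self.experiments_to_shift) - present
        if unknown:
            raise ExprMapError(f"plan names unknown experiments: {sorted(unknown)[:5]}")
        return set(self.experiments_to_shift)


def median_shift(matrix: ExpressionMatrix,
                 plan: NormalizationPlan | None = None) -> ExpressionMatrix:
    """Centre each gene's profile within each planned experiment at zero.

    For every gene and every experiment in the plan, the median of the
    gene's observed values over that experiment's conditions is subtracted
    from those values.  Genes with no observed value in an experiment are
    left untouched there; conditions of unplanned experiments pass through
    unchanged.  Idempotent and invariant to per-(gene, experiment) constant
    shifts of the input.
    """
    if plan is None:
        plan = NormalizationPlan()
    shift = plan.resolve(matrix)
    values = matrix.values.to_numpy(dtype=float, copy=True)
    cols = {c: i for i, c in enumerate(matrix.condition_ids)}
    for exp in matrix.experiment_ids:
        if exp not in shift:
            continue
        idx = [cols[c] for c in matrix.conditions_of(exp)]
        block = values[:, idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            med = np.nanmedian(block, axis=1, keepdims=True)
        med = np.where(np.isnan(med), 0.0, med)  # all-missing rows: no shift
        values[:, idx] = block - med
    out = matrix.values.copy()
    out.loc[:, :] = values
    return ExpressionMatrix(out, dict(matrix.experiment_of))
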