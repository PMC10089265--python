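"""Quality control and absolute quantification of element-cycling qPCR data.

A cycle threshold (CT) of 31 is the detection limit: relative copy number is
``E**(31 - CT)`` with ``E`` the assay's amplification efficiency (fold
amplification per cycle, nominally 2), so CT = 31 maps to one relative copy
and anything beyond the threshold — or a blank cell — is a non-detect and a
true zero downstream. Absolute copies are obtained by scaling each sample's
relative copies against its independently measured absolute 16S rRNA copy
number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CtTable, ValidationError
from .panel import FUNCTIONAL_CATEGORIES, PanelDefinition

logger = logging.getLogger(__name__)

CT_DETECTION_THRESHOLD = 31.0
EFFICIENCY_MIN = 1.8
EFFICIENCY_MAX = 2.2


@dataclass
class QuantResult:
    """Per sample × assay relative and absolute copy numbers."""

    relative: pd.DataFrame = field(repr=False)   # N0_rel = E**(31 - CT); 0 = non-detect
    absolute: pd.DataFrame | None = field(default=None, repr=False)
    efficiencies: pd.Series | None = field(default=None, repr=False)
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def detected(self) -> pd.DataFrame:
        return self.relative > 0


def qc_filter(ct: CtTable, panel: PanelDefinition) -> CtTable:
    """Drop assays whose amplification efficiency falls outside [1.8, 2.2].

    Bounds are inclusive: only E < 1.8 or E > 2.2 eliminates an assay, across
    all samples. Removals are logged; an empty result is allowed but warned.
    """
    ct.check_panel(panel)
    eff = panel.table["efficiency"]
    bad = eff.index[(eff < EFFICIENCY_MIN) | (eff > EFFICIENCY_MAX)]
    removed = [a for a in ct.assay_ids if a in set(bad)]
    if removed:
        logger.info("qc_filter removed %d assays with out-of-range efficiency: %s",
                    len(removed), removed)
    kept = [a for a in ct.assay_ids if a not in set(bad)]
    if not kept:
        warnings.warn("qc_filter removed every assay", stacklevel=2)
    return CtTable(ct.data[kept])


def ct_to_relative(
    ct_value: float,
    efficiency: float = 2.0,
    threshold: float = CT_DETECTION_THRESHOLD,
) -> float:
    """Relative copy number from a single CT value.

    NaN (blank) or CT above the detection threshold → 0.
    """
    if threshold <= 0:
        raise ValidationError("detection threshold must be positive")
    if efficiency <= 1:
        raise ValidationError(f"amplification efficiency must exceed 1, got {efficiency}")
    if ct_value is None or np.isnan(ct_value) or ct_value > threshold:
        return 0.0
    return float(efficiency ** (threshold - ct_value))


def quantify_relative(
    ct: CtTable,
    panel: PanelDefinition,
    threshold: float = CT_DETECTION_THRESHOLD,
) -> QuantResult:
    """Vectorised CT → relative copies for a whole table."""
    ct.check_panel(panel)
    eff = panel.table["efficiency"].reindex(ct.assay_ids)
    values = ct.data.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        rel = eff.to_numpy() ** (threshold - values)
    rel[np.isnan(values) | (values > threshold)] = 0.0
    relative = pd.DataFrame(rel, index=ct.data.index, columns=ct.data.columns)
    return QuantResult(relative=relative, efficiencies=eff)


def absolute_abundance(
    rel: QuantResult,
    abs_16s_copies: pd.Series,
    reference_assay: str = "16S",
) -> QuantResult:
    """Scale relative copies to absolute copies per gram of soil.

    abs_gene = N0_rel(gene) × abs_16S / N0_rel(16S), per sample. Samples
    whose 16S reference is a non-detect are flagged and excluded.
    """
    if reference_assay not in rel.relative.columns:
        raise ValidationError(f"reference assay {reference_assay!r} absent from quantification")
    abs_16s = abs_16s_copies.reindex(rel.relative.index)
    if abs_16s.isna().any():
        missing = abs_16s.index[abs_16s.isna()].tolist()
        raise ValidationError(f"samples without absolute 16S copies: {missing}")
    if (abs_16s <= 0).any():
        raise ValidationError("absolute 16S copy numbers must be positive")
    ref_rel = rel.relative[reference_assay]
    flagged = ref_rel.index[ref_rel <= 0].tolist()
    if flagged:
        warnings.warn(
            f"16S non-detect in samples {flagged}; absolute abundances undefined there",
            stacklevel=2,
        )
    genes = rel.relative.drop(columns=[reference_assay])
    scale = (abs_16s / ref_rel.where(ref_rel > 0)).astype(float)
    absolute = genes.mul(scale, axis=0)
    absolute.loc[flagged] = np.nan
    return QuantResult(
        relative=rel.relative,
        absolute=absolute,
        efficiencies=rel.efficiencies,
        flagged_samples=flagged,
    )


def quantify(
    ct: CtTable,
    panel: PanelDefinition,
    abs_16s_copies: pd.Series,
    threshold: float = CT_DETECTION_THRESHOLD,
    qc: bool = True,
) -> QuantResult:
    """Full chain: efficiency QC → relative copies → absolute copies."""
    if qc:
        ct = qc_filter(ct, panel)
    rel = quantify_relative(ct, panel, threshold=threshold)
    return absolute_abundance(rel, abs_16s_copies, reference_assay=panel.reference_assay)


def aggregate_categories(q: QuantResult, panel: PanelDefinition) -> pd.DataFrame:
    """Sum absolute copies per element-cycle category, per sample.

    Returns samples × 6 categories. Detected-gene counts are attached as a
    DataFrame attribute ``detected_counts``.
    """
    if q.absolute is None:
        raise ValidationError("aggregate_categories needs absolute abundances; run quantify first")
    cats = panel.table["category"].reindex(q.absolute.columns)
    if cats.isna().any():
        missing = cats.index[cats.isna()].tolist()
        raise ValidationError(f"uncategorized assays: {missing}")
    sums = q.absolute.T.groupby(cats.values).sum().T
    detected = (q.absolute > 0).T.groupby(cats.values).sum().T
    out = pd.DataFrame(
        {c: sums.get(c, pd.Series(0.0, index=q.absolute.index)) for c in FUNCTIONAL_CATEGORIES}
    )
    if q.flagged_samples:
        out.loc[q.flagged_samples] = np.nan
    out.attrs["detected_counts"] = pd.DataFrame(
        {c: detected.get(c, pd.Series(0, index=q.absolute.index)) for c in FUNCTIONAL_CATEGORIES}
    )
    return out
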