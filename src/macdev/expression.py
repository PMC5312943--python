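"""Time-course expression filtering, normalization and the development-specific
mRNA classifier.

The pipeline starts from a gene x sample abundance matrix (FPKM or TPM) covering
a conjugation time course: vegetative cultures plus 0, 6, 12, 24, 48 and 72
hours post-mixing, with replicates. Genes without reliable signal are removed,
abundances are log2(x+1)-transformed and expressed relative to the mean of the
0-hour samples, and an mRNA is called development-specific when its mean
relative expression at one or more developmental time points exceeds both the
0-hour and the vegetative control means by at least a fold threshold
(default 3-fold, i.e. log2(3) on the working scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical condition labels in temporal order.
CONDITIONS = ("veg", "0h", "6h", "12h", "24h", "48h", "72h")
#: Conditions eligible to carry a development-specific expression peak.
DEV_CONDITIONS = ("6h", "12h", "24h", "48h", "72h")
#: Control conditions a specific mRNA must exceed.
CONTROL_CONDITIONS = ("0h", "veg")


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample IDs to (condition, replicate index)."""

    samples: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("design contains no samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond, _ in self.samples.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s, (c, _) in self.samples.items() if c == condition]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SampleDesign":
        """Build from a table with columns sample_id, condition, replicate."""
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in design table")
        return cls(
            {
                str(r.sample_id): (str(r.condition), int(r.replicate))
                for r in table.itertuples()
            }
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, c, r) for s, (c, r) in self.samples.items()],
            columns=["sample_id", "condition", "replicate"],
        )

    @classmethod
    def default_timecourse(cls, replicates: int = 2) -> "SampleDesign":
        """The 14-sample design: two replicates of each of seven conditions."""
        return cls(
            {
                f"{cond}_r{rep}": (cond, rep)
                for cond in CONDITIONS
                for rep in range(1, replicates + 1)
            }
        )


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample abundances with declared units."""

    data: pd.DataFrame
    units: str = "FPKM"

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance matrix contains negative values")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene IDs in abundance matrix")


def _frame(expr) -> pd.DataFrame:
    return expr.data if isinstance(expr, ExpressionMatrix) else expr


def filter_quality(expr, threshold: float = 3.0, strict: bool = False):
    """Keep genes whose maximal abundance reaches ``threshold`` in >=1 sample.

    The FPKM convention is inclusive (max >= threshold); the micronuclear TPM
    variant uses ``strict=True`` (max > threshold). Gene order is preserved.
    """
    data = _frame(expr)
    if data.empty:
        raise ValueError("cannot filter an empty expression matrix")
    if threshold < 0:
        raise ValueError("quality threshold must be non-negative")
    gene_max = data.max(axis=1)
    keep = gene_max > threshold if strict else gene_max >= threshold
    out = data.loc[keep]
    if isinstance(expr, ExpressionMatrix):
        return ExpressionMatrix(out, expr.units)
    return out


def transform_normalize(expr, design: SampleDesign, reference: str = "0h") -> pd.DataFrame:
    """log2(x+1)-transform and subtract each gene's mean over reference samples.

    Returns the relative expression matrix (log2 units); by construction every
    gene's mean over the reference-condition columns is zero.
    """
    data = _frame(expr)
    missing = [c for c in data.columns if c not in design.samples]
    if missing:
        raise ValueError(f"samples absent from design: {missing}")
    ref_samples = [s for s in design.condition_samples(reference) if s in data.columns]
    if not ref_samples:
        raise ValueError(f"no '{reference}' samples present for normalization")
    logged = np.log2(data + 1.0)
    return logged.sub(logged[ref_samples].mean(axis=1), axis=0)


def condition_means(rel: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """Mean relative expression per condition (genes x conditions)."""
    cols = {}
    for cond in design.conditions:
        samples = [s for s in design.condition_samples(cond) if s in rel.columns]
        if samples:
            cols[cond] = rel[samples].mean(axis=1)
    return pd.DataFrame(cols)


def classify_preferential(
    rel: pd.DataFrame,
    design: SampleDesign,
    fold: float = 3.0,
    dev_conditions: tuple[str, ...] = DEV_CONDITIONS,
    control_conditions: tuple[str, ...] = CONTROL_CONDITIONS,
) -> pd.DataFrame:
    """Call development-specific mRNAs on the relative (log2) scale.

    A gene is specific iff some developmental condition's mean relative
    expression exceeds every control condition's mean by >= log2(fold). The
    peak condition is the argmax over developmental condition means, ties
    broken toward the earliest time point.

    Returns a frame indexed by gene with columns ``specific`` (bool),
    ``peak_condition`` and ``max_rel_log2``.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    means = condition_means(rel, design)
    devs = [c for c in dev_conditions if c in means.columns]
    if not devs:
        raise ValueError("no developmental conditions present in design")
    ctrls = [c for c in control_conditions if c in means.columns]
    if not ctrls:
        raise ValueError("no control conditions present in design")

    log_fold = np.log2(fold)
    dev_means = means[devs]
    # binding constraint: the largest control mean
    ctrl_floor = means[ctrls].max(axis=1)
    specific = (dev_means.ge(ctrl_floor + log_fold, axis=0)).any(axis=1)
    # argmax with earliest-time tie-break: idxmax scans columns left to right
    peak = dev_means.idxmax(axis=1)
    return pd.DataFrame(
        {
            "specific": specific,
            "peak_condition": peak,
            "max_rel_log2": dev_means.max(axis=1),
        }
    )


def classify_preferential_raw(
    expr,
    design: SampleDesign,
    fold: float = 3.0,
    dev_conditions: tuple[str, ...] = DEV_CONDITIONS,
    control_conditions: tuple[str, ...] = CONTROL_CONDITIONS,
) -> pd.DataFrame:
    """Alternative classifier on raw abundance ratios (config switch).

    Specific iff some developmental condition's mean raw abundance is
    >= fold x every control condition's mean raw abundance.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    data = _frame(expr)
    means = condition_means(data, design)  # raw means; works on any matrix
    devs = [c for c in dev_conditions if c in means.columns]
    ctrls = [c for c in control_conditions if c in means.columns]
    if not devs or not ctrls:
        raise ValueError("design must cover developmental and control conditions")
    dev_means = means[devs]
    ctrl_floor = means[ctrls].max(axis=1)
    specific = dev_means.ge(fold * ctrl_floor, axis=0).any(axis=1)
    peak = dev_means.idxmax(axis=1)
    return pd.DataFrame(
        {
            "specific": specific,
            "peak_condition": peak,
            "max_rel_log2": np.log2((dev_means.max(axis=1) + 1.0) / (ctrl_floor + 1.0)),
        }
    )


@dataclass
class ClassificationResult:
    """Bundled output of the filter -> transform -> classify path."""

    filtered: pd.DataFrame
    relative: pd.DataFrame
    calls: pd.DataFrame
    n_input: int = 0
    n_retained: int = field(default=0)

    @property
    def specific_genes(self) -> list[str]:
        return list(self.calls.index[self.calls["specific"]])


def run_classification(
    expr,
    design: SampleDesign,
    threshold: float = 3.0,
    fold: float = 3.0,
    strict_threshold: bool = False,
) -> ClassificationResult:
    """Full FPKM-style path: quality filter, normalize, classify."""
    data = _frame(expr)
    filtered = filter_quality(data, threshold=threshold, strict=strict_threshold)
    rel = transform_normalize(filtered, design)
    calls = classify_preferential(rel, design, fold=fold)
    logger.info(
        "classification: %d/%d genes retained, %d specific",
        len(filtered), len(data), int(calls["specific"].sum()),
    )
    return ClassificationResult(
        filtered=filtered,
        relative=rel,
        calls=calls,
        n_input=len(data),
        n_retained=len(filtered),
    )


def classify_micronuclear(tpm, design: SampleDesign, fold: float = 3.0) -> pd.DataFrame:
    """TPM variant of the classifier for micronucleus-encoded mRNAs.

    Identical pipeline except the quality threshold is strict (TPM > 3
    required in at least one sample).
    """
    if isinstance(tpm, ExpressionMatrix) and tpm.units.upper() != "TPM":
        raise ValueError("micronuclear classification requires TPM units")
    return run_classification(tpm, design, threshold=3.0, fold=fold, strict_threshold=True).calls
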