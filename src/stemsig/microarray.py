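"""Bead-summary preprocessing: background correction, quantile
normalization, and negative-control-based detection p-values.

The expression matrix is genes x samples of nonnegative fluorescence
signals; each sample additionally carries a vector of negative-control
bead signals drawn from the array's background distribution.  A gene is
called *expressed* in a sample when its empirical upper-tail p-value
against that sample's negative controls falls at or below ``alpha``
(default 0.05).

Detection p-values are rank-based and should be computed on signals that
share a scale with the controls.  Note that the epsilon floor applied by
:func:`background_correct` creates ties at the floor which, under the
"ties count as exceedances" rule, inflate p-values for sub-background
signals; for calibrated p-values compute detection on the raw matrix
(background correction cancels in the rank comparison anyway whenever no
value hits the floor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

MIN_CONTROLS = 100


class BeadSummaryError(ValueError):
    """Raised for inconsistent bead-summary inputs."""


@dataclass
class BeadSummaryMatrix:
    """Genes x samples signal matrix with per-sample negative controls.

    Parameters
    ----------
    signals : pandas.DataFrame
        Rows are gene IDs, columns sample IDs, values nonnegative
        fluorescence signals.
    neg_controls : pandas.DataFrame
        Rows are control beads, columns the same sample IDs.
    groups : dict
        Maps every sample ID to its group name (e.g. fMSC, iPSC).
    """

    signals: pd.DataFrame
    neg_controls: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.signals.isna().any().any():
            raise BeadSummaryError("signal matrix contains missing values")
        if list(self.neg_controls.columns) != list(self.signals.columns):
            raise BeadSummaryError(
                "negative-control columns do not match signal columns"
            )
        missing = [s for s in self.signals.columns if s not in self.groups]
        if missing:
            raise BeadSummaryError(f"samples without a group: {missing}")
        if len(self.neg_controls) == 0:
            raise BeadSummaryError("no negative-control values")
        if len(self.neg_controls) < MIN_CONTROLS:
            warnings.warn(
                f"only {len(self.neg_controls)} negative controls per sample; "
                f"p-value granularity is 1/{len(self.neg_controls) + 1}",
                stacklevel=2,
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]


@dataclass
class DetectionResult:
    """Per-gene, per-sample detection p-values and expression calls."""

    p: pd.DataFrame
    alpha: float = 0.05
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def expressed(self) -> pd.DataFrame:
        """Boolean calls: expressed iff p <= alpha."""
        return self.p <= self.alpha


def background_correct(
    matrix: BeadSummaryMatrix, eps: float = 1.0
) -> BeadSummaryMatrix:
    """Subtract each sample's median negative-control signal.

    Results are floored at ``eps`` (a small positive signal unit) so that
    downstream log transforms stay defined.  Controls are corrected with
    the same per-sample offset and floor.
    """
    if len(matrix.neg_controls) == 0:  # pragma: no cover - guarded in ctor
        raise BeadSummaryError("cannot background-correct without controls")
    medians = matrix.neg_controls.median(axis=0)
    signals = (matrix.signals - medians).clip(lower=eps)
    controls = (matrix.neg_controls - medians).clip(lower=eps)
    return BeadSummaryMatrix(signals, controls, dict(matrix.groups))


def quantile_normalize(signals: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns.  Within a
    column, tied input values receive the mean of the reference quantiles
    spanned by their ranks, which makes the result independent of the
    input row order.
    """
    if signals.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = np.asarray(signals, dtype=float)
    srt = np.sort(x, axis=0)
    ref = srt.mean(axis=1)
    # the mean of identical values is that value, bit-exactly: this keeps
    # repeated normalization a true fixed point
    constant_rows = (srt == srt[:, :1]).all(axis=1)
    ref[constant_rows] = srt[constant_rows, 0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = _map_to_reference(x[:, j], ref)
    return pd.DataFrame(out, index=signals.index, columns=signals.columns)


def _map_to_reference(col: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="stable")
    mapped = np.empty(len(col))
    sorted_vals = col[order]
    # runs of equal input values share the mean of their reference span
    i = 0
    n = len(col)
    while i < n:
        j = i + 1
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        mapped[order[i:j]] = ref[i:j].mean()
        i = j
    return mapped


def detection_pvalues(
    matrix: BeadSummaryMatrix, alpha: float = 0.05
) -> DetectionResult:
    """Empirical upper-tail p-value of each signal against its sample's
    negative-control distribution.

    ``p[g, s] = (1 + #{controls in s >= signal[g, s]}) / (n_controls + 1)``
    with ties counted as exceedances; the add-one form keeps p strictly
    positive.
    """
    n = len(matrix.neg_controls)
    if n == 0:  # pragma: no cover - guarded in ctor
        raise BeadSummaryError("no negative controls")
    p = np.empty(matrix.signals.shape)
    x = np.asarray(matrix.signals, dtype=float)
    ctrl = np.asarray(matrix.neg_controls, dtype=float)
    for j in range(x.shape[1]):
        c = np.sort(ctrl[:, j])
        # controls >= signal, ties included
        n_ge = n - np.searchsorted(c, x[:, j], side="left")
        p[:, j] = (1.0 + n_ge) / (n + 1.0)
    frame = pd.DataFrame(
        p, index=matrix.signals.index, columns=matrix.signals.columns
    )
    return DetectionResult(frame, alpha=alpha, groups=dict(matrix.groups))


def group_detection(
    det: DetectionResult,
    group: str | list[str],
    policy: str = "max",
) -> pd.Series:
    """Combine a group's per-sample detection p-values into one per gene.

    Policies
    --------
    ``"max"``
        Per-gene maximum over the group's samples: conservative for
        "expressed in the whole group" (< threshold) readings.
    ``"min"``
        Per-gene minimum: conservative for "absent in the whole group".
    ``"single:SAMPLE_ID"``
        That sample's column alone, reproducing single-sample figures.

    ``group`` may be a single group name or a list of names whose samples
    are pooled (e.g. ``["fMSC", "aMSC"]`` for the combined MSC reading).
    """
    names = [group] if isinstance(group, str) else list(group)
    samples = [s for s in det.p.columns if det.groups.get(s) in names]
    if policy.startswith("single:"):
        sid = policy.split(":", 1)[1]
        if sid not in det.p.columns:
            raise KeyError(f"unknown sample {sid!r}")
        return det.p[sid]
    if not samples:
        raise KeyError(f"no samples in group(s) {names}")
    if policy == "max":
        return det.p[samples].max(axis=1)
    if policy == "min":
        return det.p[samples].min(axis=1)
    raise ValueError(f"unknown policy {policy!r}")


def read_bead_summary(
    signals_path, controls_path, groups_path
) -> BeadSummaryMatrix:
    """Read the tab-separated bead-summary dialect.

    ``signals_path``: genes x samples TSV, first column gene IDs, header
    row of sample IDs.  ``controls_path``: control beads x samples TSV
    with the same sample columns.  ``groups_path``: YAML/JSON mapping
    sample ID -> group name.
    """
    signals = pd.read_csv(signals_path, sep="\t", index_col=0)
    controls = pd.read_csv(controls_path, sep="\t", index_col=0)
    with open(groups_path) as fh:
        groups = yaml.safe_load(fh)
    return BeadSummaryMatrix(signals, controls, groups)


def write_bead_summary(matrix: BeadSummaryMatrix, signals_path, controls_path, groups_path) -> None:
    """Serialize a bead-summary matrix to the TSV + YAML dialect."""
    matrix.signals.to_csv(signals_path, sep="\t")
    matrix.neg_controls.to_csv(controls_path, sep="\t")
    with open(groups_path, "w") as fh:
        yaml.safe_dump(dict(matrix.groups), fh)
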