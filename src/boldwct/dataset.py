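"""Cohorts of ROI BOLD time series: containers, I/O, truncation, balancing.

A recording is a ``(time points x nodes)`` matrix of BOLD amplitudes for one
subject, parcellated into a fixed set of brain nodes (116 for the AAL atlas).
Multi-site cohorts arrive with unequal scan lengths and unequal group sizes;
this module provides the two harmonisation steps applied before any spectral
analysis: truncation of every recording to the shortest common length and
random down-sampling of each diagnostic group to the smallest group size.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Diagnostic labels: three DSM-4 autism-spectrum subtypes plus normal controls.
DEFAULT_GROUPS = ("ASD", "APD", "PDD-NOS", "NC")

MIN_TIMEPOINTS = 16


class CohortError(ValueError):
    """Raised for structurally invalid cohorts or recordings."""


@dataclasses.dataclass
class RoiTimeSeries:
    """One subject's parcellated BOLD recording plus acquisition metadata."""

    subject_id: str
    site: str
    group: str
    data: np.ndarray  # (n_timepoints, n_nodes), float
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise CohortError(
                f"subject {self.subject_id}: data must be 2-D (time x nodes), "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise CohortError(f"subject {self.subject_id}: non-finite values in data")
        if self.data.shape[1] < 2:
            raise CohortError(f"subject {self.subject_id}: need >= 2 nodes")
        if self.data.shape[0] < MIN_TIMEPOINTS:
            raise CohortError(
                f"subject {self.subject_id}: need >= {MIN_TIMEPOINTS} time points, "
                f"got {self.data.shape[0]}"
            )
        if not self.tr_seconds > 0:
            raise CohortError(f"subject {self.subject_id}: tr_seconds must be > 0")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class Cohort:
    """A list of recordings sharing one parcellation."""

    recordings: list[RoiTimeSeries]
    node_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.recordings:
            n_nodes = {r.n_nodes for r in self.recordings}
            if len(n_nodes) != 1:
                raise CohortError(f"inconsistent node counts across recordings: {sorted(n_nodes)}")
        if self.node_names is not None and self.recordings:
            if len(self.node_names) != self.recordings[0].n_nodes:
                raise CohortError(
                    f"node_names length {len(self.node_names)} does not match "
                    f"node count {self.recordings[0].n_nodes}"
                )

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def n_nodes(self) -> int:
        if not self.recordings:
            raise CohortError("empty cohort has no node count")
        return self.recordings[0].n_nodes

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: list[str] = []
        for r in self.recordings:
            if r.group not in seen:
                seen.append(r.group)
        return seen

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for r in self.recordings:
            sizes[r.group] = sizes.get(r.group, 0) + 1
        return sizes

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort([self.recordings[i] for i in indices], node_names=self.node_names)


def load_cohort(
    manifest_path: str | Path,
    allowed_groups: Sequence[str] = DEFAULT_GROUPS,
) -> Cohort:
    """Load a cohort described by a manifest CSV.

    The manifest has columns ``subject_id, site, group, tr_seconds,
    n_timepoints, file``; each ``file`` is a tab-separated matrix with rows =
    time points and columns = nodes (no header), resolved relative to the
    manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CohortError(f"manifest not found: {manifest_path}")
    table = pd.read_csv(manifest_path, dtype={"subject_id": str, "site": str, "group": str})
    required = {"subject_id", "site", "group", "tr_seconds", "n_timepoints", "file"}
    missing = required - set(table.columns)
    if missing:
        raise CohortError(f"manifest missing columns: {sorted(missing)}")

    base = manifest_path.parent
    recordings: list[RoiTimeSeries] = []
    for row in table.itertuples(index=False):
        if row.group not in allowed_groups:
            raise CohortError(
                f"subject {row.subject_id}: unknown group label {row.group!r} "
                f"(allowed: {list(allowed_groups)})"
            )
        path = base / str(row.file)
        if not path.exists():
            raise CohortError(f"subject {row.subject_id}: time-series file missing: {path}")
        try:
            data = np.loadtxt(path, delimiter="\t", ndmin=2)
        except Exception as exc:  # noqa: BLE001 - rewrap with subject context
            raise CohortError(f"subject {row.subject_id}: cannot read {path}: {exc}") from exc
        if data.shape[0] != int(row.n_timepoints):
            raise CohortError(
                f"subject {row.subject_id}: file has {data.shape[0]} time points, "
                f"manifest says {int(row.n_timepoints)}"
            )
        recordings.append(
            RoiTimeSeries(
                subject_id=str(row.subject_id),
                site=str(row.site),
                group=str(row.group),
                data=data,
                tr_seconds=float(row.tr_seconds),
            )
        )
    return Cohort(recordings)


def truncate_to_common_length(cohort: Cohort) -> Cohort:
    """Truncate every recording to the shortest length in the cohort.

    The leading segment (from time index 0) is kept, so retained samples are
    unaltered. Idempotent.
    """
    if not cohort.recordings:
        raise CohortError("cannot truncate an empty cohort")
    t_min = min(r.n_timepoints for r in cohort.recordings)
    out = [
        dataclasses.replace(r, data=r.data[:t_min].copy()) if r.n_timepoints > t_min else r
        for r in cohort.recordings
    ]
    return Cohort(out, node_names=cohort.node_names)


def balance_groups(
    cohort: Cohort,
    seed: int,
    groups: Optional[Sequence[str]] = None,
) -> Cohort:
    """Down-sample each group to the smallest group size.

    Selection within a group is uniform without replacement, driven by
    ``seed``; the relative order of retained subjects is preserved. With
    ``groups`` given, every listed group must be present.
    """
    if not cohort.recordings:
        raise CohortError("cannot balance an empty cohort")
    present = cohort.group_sizes()
    wanted = list(groups) if groups is not None else cohort.groups
    absent = [g for g in wanted if g not in present]
    if absent:
        raise CohortError(f"groups absent from cohort: {absent}")

    n_min = min(present[g] for g in wanted)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for g in wanted:
        idx = [i for i, r in enumerate(cohort.recordings) if r.group == g]
        chosen = rng.choice(len(idx), size=n_min, replace=False)
        keep.extend(idx[j] for j in sorted(chosen))
    keep.sort()
    return cohort.subset(keep)
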