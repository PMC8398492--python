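"""Synthetic multi-site BOLD-like cohorts with planted group effects.

The generator emulates the statistical structure that the downstream pipeline
is designed to detect, without any real scan: each node carries a sum of
band-limited (0.01-0.1 Hz) sinusoidal oscillations plus white noise, sampled
at a repetition time of typically 2 s.  Two group effects are planted:

* **spectral power** — the oscillation amplitude of one designated node is
  multiplied by a per-group factor, so a Welch-PSD ANOVA across groups can
  single that node out;
* **phase coupling** — a designated subset of partner nodes shares the
  planted node's oscillatory components with per-group mixing weight ``c``
  (partner = c * shared + sqrt(1-c^2) * private), so wavelet coherence
  between the planted node and its partners is approximately ``c^2`` inside
  the oscillation band, while the partner's marginal power is unchanged.

Site heterogeneity is modelled as a linear gain and offset applied last,
which makes the per-subject normalisation step downstream consequential.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import Cohort, RoiTimeSeries, DEFAULT_GROUPS, MIN_TIMEPOINTS


class SpecError(ValueError):
    """Raised when a CohortSpec field is invalid; the message names the field."""


@dataclasses.dataclass(frozen=True)
class SiteSpec:
    """One acquisition site: subject quota and linear signal distortion."""

    site_id: str
    n_subjects: int
    gain: float = 1.0
    offset: float = 0.0


def _default_sites(n_total: int) -> tuple[SiteSpec, ...]:
    """Four sites with near-equal quotas and mild gain/offset differences."""
    base, extra = divmod(n_total, 4)
    quotas = [base + (1 if i < extra else 0) for i in range(4)]
    gains = (1.0, 1.2, 0.85, 1.1)
    offsets = (0.0, 6.0, -4.0, 2.5)
    return tuple(
        SiteSpec(site_id=f"site{chr(ord('A') + i)}", n_subjects=q, gain=g, offset=o)
        for i, (q, g, o) in enumerate(zip(quotas, gains, offsets))
    )


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults emulate a balanced four-group study (36 subjects per group,
    116 nodes, 145 time points at TR = 2 s) in which spectral power at the
    planted node is ordered ASD > APD > PDD-NOS > NC and phase coupling to
    the partner nodes decreases in the same order.
    """

    n_per_group: int = 36
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_nodes: int = 116
    n_timepoints: int = 145
    tr_seconds: float = 2.0
    sites: Optional[tuple[SiteSpec, ...]] = None
    planted_node: Optional[int] = None  # default: node 5, clipped to range
    partner_nodes: Optional[tuple[int, ...]] = None
    power_effects: Optional[dict[str, float]] = None
    coupling_effects: Optional[dict[str, float]] = None
    noise_sd: float = 0.5
    n_oscillations: int = 3
    freq_band: tuple[float, float] = (0.01, 0.1)
    rng_seed: int = 0

    _DEFAULT_POWER = (1.6, 1.4, 1.2, 1.0)
    _DEFAULT_COUPLING = (0.9, 0.7, 0.5, 0.1)

    def __post_init__(self) -> None:
        if self.planted_node is None:
            self.planted_node = min(5, self.n_nodes - 1)
        if self.power_effects is None:
            scale = self._DEFAULT_POWER
            self.power_effects = {
                g: scale[i] if i < len(scale) else 1.0 for i, g in enumerate(self.groups)
            }
        if self.coupling_effects is None:
            scale = self._DEFAULT_COUPLING
            self.coupling_effects = {
                g: scale[i] if i < len(scale) else 0.1 for i, g in enumerate(self.groups)
            }
        if self.sites is None:
            self.sites = _default_sites(self.n_total)
        if self.partner_nodes is None:
            n_partners = min(10, self.n_nodes - 1)
            self.partner_nodes = tuple(
                (self.planted_node + 1 + k) % self.n_nodes for k in range(n_partners)
            )
        self.validate()

    @property
    def n_total(self) -> int:
        return self.n_per_group * len(self.groups)

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise SpecError("n_per_group must be >= 1")
        if len(self.groups) < 1 or len(set(self.groups)) != len(self.groups):
            raise SpecError("groups must be non-empty and unique")
        if self.n_nodes < 2:
            raise SpecError("n_nodes must be >= 2")
        if self.n_timepoints < MIN_TIMEPOINTS:
            raise SpecError(f"n_timepoints must be >= {MIN_TIMEPOINTS}")
        if not self.tr_seconds > 0:
            raise SpecError("tr_seconds must be > 0")
        if not 0 <= self.planted_node < self.n_nodes:
            raise SpecError("planted_node out of range")
        assert self.sites is not None and self.partner_nodes is not None
        quota = sum(s.n_subjects for s in self.sites)
        if quota != self.n_total:
            raise SpecError(
                f"sites: subject quotas sum to {quota}, expected "
                f"n_per_group x n_groups = {self.n_total}"
            )
        for p in self.partner_nodes:
            if not 0 <= p < self.n_nodes or p == self.planted_node:
                raise SpecError("partner_nodes must be valid indices distinct from planted_node")
        for name, table in (("power_effects", self.power_effects),
                            ("coupling_effects", self.coupling_effects)):
            assert table is not None
            missing = [g for g in self.groups if g not in table]
            if missing:
                raise SpecError(f"{name} missing entries for groups {missing}")
        for g, c in self.coupling_effects.items():
            if not 0.0 <= c <= 1.0:
                raise SpecError(f"coupling_effects[{g!r}] must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.n_oscillations < 1:
            raise SpecError("n_oscillations must be >= 1")
        lo, hi = self.freq_band
        if not (0 < lo < hi <= 0.5 / self.tr_seconds):
            raise SpecError("freq_band must satisfy 0 < low < high <= Nyquist")


def _assignments(spec: CohortSpec) -> list[tuple[SiteSpec, str, int]]:
    """Deterministic (site, group, within-site-group index) per subject.

    Subjects are dealt group-interleaved into site quotas so every group is
    spread across sites (mirroring a multi-site study).
    """
    assert spec.sites is not None
    slots: list[SiteSpec] = []
    for site in spec.sites:
        slots.extend([site] * site.n_subjects)
    out: list[tuple[SiteSpec, str, int]] = []
    counters: dict[tuple[str, str], int] = {}
    pos = 0
    for _ in range(spec.n_per_group):
        for g in spec.groups:
            site = slots[pos]
            pos += 1
            k = counters.get((site.site_id, g), 0)
            counters[(site.site_id, g)] = k + 1
            out.append((site, g, k))
    return out


def _oscillation(rng: np.random.Generator, spec: CohortSpec, t: np.ndarray) -> np.ndarray:
    freqs = rng.uniform(*spec.freq_band, size=spec.n_oscillations)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_oscillations)
    return np.sin(2.0 * np.pi * t[:, None] * freqs[None, :] + phases[None, :]).sum(axis=1)


def _phase_locked(rng: np.random.Generator, spec: CohortSpec, t: np.ndarray,
                  freqs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Same components as the planted oscillation, with one random lag."""
    lag = rng.uniform(0.0, 2.0 * np.pi)
    return np.sin(2.0 * np.pi * t[:, None] * freqs[None, :]
                  + phases[None, :] + lag).sum(axis=1)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate one recording per subject; bit-identical for identical spec."""
    spec.validate()
    assert spec.sites is not None and spec.partner_nodes is not None
    site_index = {s.site_id: i for i, s in enumerate(spec.sites)}
    group_index = {g: i for i, g in enumerate(spec.groups)}
    t = np.arange(spec.n_timepoints) * spec.tr_seconds
    partners = set(spec.partner_nodes)

    recordings: list[RoiTimeSeries] = []
    for subj_no, (site, group, k) in enumerate(_assignments(spec)):
        # independent, reproducible stream per (site, group, within-index)
        rng = np.random.default_rng(
            [spec.rng_seed, site_index[site.site_id], group_index[group], k]
        )
        freqs = rng.uniform(*spec.freq_band, size=spec.n_oscillations)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_oscillations)
        planted_osc = np.sin(
            2.0 * np.pi * t[:, None] * freqs[None, :] + phases[None, :]
        ).sum(axis=1)

        amp = spec.power_effects[group]
        coup = spec.coupling_effects[group]
        data = np.empty((spec.n_timepoints, spec.n_nodes))
        for j in range(spec.n_nodes):
            if j == spec.planted_node:
                sig = amp * planted_osc
            elif j in partners:
                shared = _phase_locked(rng, spec, t, freqs, phases)
                own = _oscillation(rng, spec, t)
                sig = coup * shared + np.sqrt(1.0 - coup**2) * own
            else:
                sig = _oscillation(rng, spec, t)
            data[:, j] = sig
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
        data = site.gain * data + site.offset

        recordings.append(
            RoiTimeSeries(
                subject_id=f"sub-{subj_no:04d}",
                site=site.site_id,
                group=group,
                data=data,
                tr_seconds=spec.tr_seconds,
            )
        )
    return Cohort(recordings)


def write_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write one TSV per subject plus a manifest CSV; returns the manifest path.

    Values are written with 17 significant digits so a round trip through
    :func:`boldwct.dataset.load_cohort` is exact.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc

    rows = []
    for r in cohort.recordings:
        fname = f"{r.subject_id}.tsv"
        path = directory / fname
        try:
            np.savetxt(path, r.data, fmt="%.17g", delimiter="\t")
        except OSError as exc:
            raise OSError(f"cannot write time series to {path}: {exc}") from exc
        rows.append(
            {
                "subject_id": r.subject_id,
                "site": r.site,
                "group": r.group,
                "tr_seconds": r.tr_seconds,
                "n_timepoints": r.n_timepoints,
                "file": fname,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
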