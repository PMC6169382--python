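"""Synthetic DNA-content flow cytometry and ploidy peak calling.

Microsatellites cannot distinguish a true triploid from a mosaic of
diploid cell lines — both show three alleles at multiple loci. DNA
flow cytometry can: DAPI fluorescence of a nucleus scales with DNA
content, so haploid, diploid, triploid and tetraploid nuclei form
C1/C2/C3/C4 peaks at 1x, 2x, 3x and 4x the haploid reference
intensity. A triploid bee's brain is C3-dominant; a diploid mosaic's
is C2-dominant.

This module synthesises fluorescence event lists (Gaussian mixture
components at integer multiples of the C1 mean, common coefficient of
variation) and calls peak proportions by nearest-expected-peak gating
against a haploid calibration sample — the standards-based approach
used with real cytometer data, where drone brain defines C1 and worker
brain C2. Tissue matters: thorax undergoes autopolyploidization (a
drone's thorax reads C2 despite his haploid genome), brain does not,
so brain is the ploidy-informative tissue.

Group comparison between 2-allele and 3-allele bees is rank-based
(Mann-Whitney) with a bootstrap confidence interval on the difference
of mean peak fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CytometrySample",
    "PloidyComposition",
    "synthesize_histogram",
    "call_peaks",
    "compare_groups",
    "PRESETS",
]

COMPONENTS = ("C1", "C2", "C3", "C4")
MIN_EVENTS = 100
# Gate half-width as a fraction of the C1 reference. Peaks sit one C1 unit
# apart, so any value < 0.5 keeps the gates disjoint; because instrument
# spread scales with intensity (constant CV), a narrow gate preferentially
# discards high-ploidy nuclei and biases the called fractions, hence a
# default close to the disjointness limit.
DEFAULT_GATE_HALFWIDTH = 0.45


@dataclass
class PloidyComposition:
    """Fractions of nuclei per DNA-content class C1..C4 (sum to 1)."""

    fractions: dict

    def __post_init__(self):
        bad = set(self.fractions) - set(COMPONENTS)
        if bad:
            raise ValueError(f"unknown components {bad}")
        vals = [self.fractions.get(c, 0.0) for c in COMPONENTS]
        if any(v < 0 for v in vals):
            raise ValueError("fractions must be >= 0")
        if not np.isclose(sum(vals), 1.0):
            raise ValueError(f"fractions sum to {sum(vals)}, not 1")
        self.fractions = {c: self.fractions.get(c, 0.0) for c in COMPONENTS}

    def __getitem__(self, component: str) -> float:
        return self.fractions[component]

    @property
    def modal(self) -> str:
        return max(COMPONENTS, key=lambda c: self.fractions[c])


@dataclass
class CytometrySample:
    """An event list of DAPI fluorescence intensities for one tissue."""

    events: np.ndarray
    tissue: str
    individual_id: str

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if np.any(self.events <= 0):
            raise ValueError("fluorescence intensities must be positive")


#: Tissue presets mirroring typical samples: brain reflects the true
#: karyotype; thorax autopolyploidises (a haploid drone's thorax reads C2).
#: A C4 shoulder of dividing cells is always present at low frequency.
PRESETS: Mapping[str, PloidyComposition] = {
    "haploid_brain": PloidyComposition({"C1": 0.90, "C2": 0.08, "C4": 0.02}),
    "haploid_thorax": PloidyComposition({"C1": 0.10, "C2": 0.85, "C4": 0.05}),
    "diploid_brain": PloidyComposition({"C2": 0.90, "C4": 0.10}),
    "diploid_thorax": PloidyComposition({"C2": 0.75, "C4": 0.25}),
    "triploid_brain": PloidyComposition({"C2": 0.05, "C3": 0.90, "C4": 0.05}),
    "triploid_thorax": PloidyComposition({"C2": 0.10, "C3": 0.75, "C4": 0.15}),
}


def synthesize_histogram(
    composition: PloidyComposition,
    n_events: int = 20000,
    c1_mean: float = 100.0,
    cv: float = 0.05,
    rng: Union[np.random.Generator, int, None] = None,
    tissue: str = "brain",
    individual_id: str = "sample",
) -> CytometrySample:
    """Draw fluorescence events from a Ck mixture.

    Component Ck is Gaussian with mean ``k * c1_mean`` and standard
    deviation ``cv * k * c1_mean``; draws are truncated to positive
    intensities. ``cv`` must lie in (0, 0.3].
    """
    if not 0.0 < cv <= 0.3:
        raise ValueError("cv must be in (0, 0.3]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    probs = np.array([composition[c] for c in COMPONENTS])
    ks = rng.choice(np.arange(1, 5), size=n_events, p=probs)
    means = ks * c1_mean
    events = rng.normal(means, cv * means)
    while np.any(events <= 0):  # redraw the rare non-physical tail
        bad = events <= 0
        events[bad] = rng.normal(means[bad], cv * means[bad])
    return CytometrySample(events=events, tissue=tissue, individual_id=individual_id)


def call_peaks(
    sample: CytometrySample,
    c1_reference: float,
    gate_halfwidth: float = DEFAULT_GATE_HALFWIDTH,
) -> PloidyComposition:
    """Assign events to C1..C4 gates around multiples of the C1 reference.

    ``c1_reference`` is the modal intensity of a haploid calibration
    sample (drone brain). Each event joins the nearest ``k *
    c1_reference`` bin (k = 1..4) if within ``gate_halfwidth *
    c1_reference`` of it; other events are discarded as debris or
    aggregates. Gates are disjoint for half-widths < 0.5. Requires at
    least 100 retained events.
    """
    if not 0 < gate_halfwidth < 0.5:
        raise ValueError("gate_halfwidth must be in (0, 0.5)")
    expected = np.arange(1, 5) * c1_reference
    dist = np.abs(sample.events[:, None] - expected[None, :])
    nearest = dist.argmin(axis=1)
    in_gate = dist[np.arange(len(sample.events)), nearest] <= gate_halfwidth * c1_reference
    kept = nearest[in_gate]
    if len(kept) < MIN_EVENTS:
        raise ValueError(
            f"only {len(kept)} events in gates; need >= {MIN_EVENTS} for calling"
        )
    counts = np.bincount(kept, minlength=4)
    fracs = counts / counts.sum()
    return PloidyComposition(dict(zip(COMPONENTS, fracs)))


def compare_groups(
    calls: pd.DataFrame,
    components: Sequence[str] = ("C2", "C3"),
    n_boot: int = 2000,
    rng: Union[np.random.Generator, int, None] = None,
) -> pd.DataFrame:
    """Compare per-bee peak fractions between allele-count groups.

    ``calls`` needs columns ``individual_id, tissue, group`` plus one
    column per component fraction (``C1``..``C4``); ``group`` holds the
    two labels (e.g. ``"2-allele"``/``"3-allele"``). For each tissue
    and component the two groups are compared by a two-sided
    Mann-Whitney U test, with a bootstrap percentile CI on the
    difference of group means (first group minus second, groups in
    sorted label order). Returns a tidy DataFrame.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    groups = sorted(calls["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    rows = []
    for tissue, sub in calls.groupby("tissue"):
        a = sub[sub["group"] == groups[0]]
        b = sub[sub["group"] == groups[1]]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"tissue {tissue}: need >= 2 bees per group")
        for comp in components:
            xa, xb = a[comp].to_numpy(float), b[comp].to_numpy(float)
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            diff = xa.mean() - xb.mean()
            boots = np.empty(n_boot)
            for i in range(n_boot):
                boots[i] = (
                    rng.choice(xa, len(xa)).mean() - rng.choice(xb, len(xb)).mean()
                )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                dict(
                    tissue=tissue,
                    component=comp,
                    group_a=groups[0],
                    group_b=groups[1],
                    mean_diff=diff,
                    ci_low=lo,
                    ci_high=hi,
                    u_statistic=res.statistic,
                    p_value=res.pvalue,
                )
            )
    return pd.DataFrame(rows)


# --- event-list I/O: CSV individual_id,tissue,intensity -------------------


def write_events_csv(samples: Sequence[CytometrySample], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "individual_id": s.individual_id,
                "tissue": s.tissue,
                "intensity": s.events,
            }
        )
        for s in samples
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_events_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for (iid, tissue), sub in df.groupby(["individual_id", "tissue"], sort=True):
        out.append(
            CytometrySample(
                events=sub["intensity"].to_numpy(float), tissue=tissue,
                individual_id=str(iid),
            )
        )
    return out
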