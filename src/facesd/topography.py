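"""Vector-scaled topographic comparison of the LPP distance-range effects.

A difference in raw amplitude between two conditions can reflect either a
stronger response of the same neural sources or a different configuration of
sources.  Dividing each participant's condition-difference topography by its
Euclidean norm over the analyzed channels (vector scaling, the
McCarthy-Wood procedure) removes overall amplitude, so a factorial ANOVA on
the scaled values compares topographic *shape*: a contrast-by-region (or
contrast-by-hemisphere) interaction then indicates distinct generator
configurations rather than a gain change.

Here the two contrasts are the far-minus-middle and close-minus-middle LPP
(400-600 ms) difference topographies on 18 representative channels grouped
into frontocentral, centroparietal and posterior regions crossed with
left/midline/right hemisphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import art_anova
from .erp import ConditionAverages, DISTANCE_CONTRASTS

__all__ = [
    "TopoSpec",
    "DEFAULT_TOPO_SPEC",
    "channel_hemisphere",
    "lpp_difference_topographies",
    "vector_scale",
    "topo_anova",
]


def channel_hemisphere(name: str) -> str:
    """Hemisphere of a 10-20 channel: odd numbers left, even right, z midline."""
    tail = name.rstrip("0123456789")
    digits = name[len(tail):]
    if not digits:
        if name.lower().endswith("z") or name in ("Iz",):
            return "midline"
        raise ValueError(f"cannot infer hemisphere for channel '{name}'")
    return "left" if int(digits) % 2 == 1 else "right"


@dataclass(frozen=True)
class TopoSpec:
    """Representative channel sets and analysis window for the topographic
    ANOVA.  The centroparietal set lists CP5 without CP6, as specified;
    the resulting left-heavy cell is noted at run time."""

    regions: dict = field(
        default_factory=lambda: {
            "frontocentral": ("Fz", "FC1", "FC2", "FCz"),
            "centroparietal": ("C3", "C4", "Cz", "CP1", "CP2", "CP5"),
            "posterior": ("Pz", "P4", "O2", "P3", "O1", "Iz", "PO9", "P7"),
        }
    )
    window_ms: tuple = (400.0, 600.0)
    reference: str = "linked_mastoid"

    def __post_init__(self) -> None:
        all_ch = [ch for chans in self.regions.values() for ch in chans]
        if len(all_ch) != len(set(all_ch)):
            raise ValueError("region channel sets must be disjoint")

    @property
    def channels(self) -> list:
        return [ch for chans in self.regions.values() for ch in chans]

    def assignments(self) -> pd.DataFrame:
        rows = [
            {"channel": ch, "region": reg, "hemisphere": channel_hemisphere(ch)}
            for reg, chans in self.regions.items()
            for ch in chans
        ]
        return pd.DataFrame(rows)


DEFAULT_TOPO_SPEC = TopoSpec()


def lpp_difference_topographies(
    avgs_by_bin: ConditionAverages,
    spec: TopoSpec = DEFAULT_TOPO_SPEC,
    contrasts=DISTANCE_CONTRASTS,
) -> pd.DataFrame:
    """Per-participant condition-difference amplitudes per channel.

    For each contrast (e.g. far minus middle), the window-mean amplitude
    difference on every representative channel.  Long format with columns
    participant, contrast, channel, amplitude.
    """
    sub = (
        avgs_by_bin.rereference(spec.reference)
        .pick_channels(spec.channels)
        .crop(spec.window_ms)
    )
    rows = []
    for hi, lo in contrasts:
        diff = sub.condition(hi) - sub.condition(lo)  # (subj, ch, t)
        amp = diff.mean(axis=2)
        for i, p in enumerate(sub.participants):
            for j, ch in enumerate(spec.channels):
                rows.append(
                    {
                        "participant": p,
                        "contrast": f"{hi}_vs_{lo}",
                        "channel": ch,
                        "amplitude": amp[i, j],
                    }
                )
    return pd.DataFrame(rows)


def vector_scale(
    topo: pd.DataFrame, per_region: bool = False, spec: TopoSpec = DEFAULT_TOPO_SPEC
) -> pd.DataFrame:
    """Divide each participant x contrast channel vector by its Euclidean
    norm (jointly over all analyzed channels by default, or within each
    region with ``per_region=True``).

    After scaling every participant x contrast vector has unit norm, so two
    topographies that differ only by a positive gain become identical.
    Zero-norm vectors cannot be scaled; those participants are dropped with
    a warning.
    """
    out = topo.copy()
    group = ["participant", "contrast"]
    if per_region:
        assign = spec.assignments().set_index("channel")["region"]
        out["_region"] = out["channel"].map(assign)
        group = group + ["_region"]
    norms = out.groupby(group)["amplitude"].transform(lambda v: np.sqrt((v**2).sum()))
    bad = norms == 0
    if bad.any():
        dropped = out.loc[bad, "participant"].unique().tolist()
        warnings.warn(f"zero-norm topography for participant(s) {dropped}; dropped")
        out = out[~bad]
        norms = norms[~bad]
    out["amplitude"] = out["amplitude"] / norms
    return out.drop(columns=["_region"], errors="ignore")


def topo_anova(
    scaled: pd.DataFrame,
    spec: TopoSpec = DEFAULT_TOPO_SPEC,
    compute_bfs: bool = True,
) -> pd.DataFrame:
    """Three-way ART ANOVA of the vector-scaled topographies.

    Within-participant factors: contrast (2) x region (3) x hemisphere (3).
    Each region x hemisphere cell is the mean over its member channels
    (keeping the design balanced despite unequal set sizes); with the
    specified sets every cell is non-empty, but any empty cell would be
    dropped with a warning.
    """
    assign = spec.assignments()
    merged = scaled.merge(assign, on="channel")
    cells = (
        merged.groupby(
            ["participant", "contrast", "region", "hemisphere"], observed=True
        )["amplitude"]
        .mean()
        .reset_index()
    )
    n_cells = cells.groupby(["region", "hemisphere"], observed=True).size()
    expected = len(spec.regions) * 3
    if len(n_cells) < expected:
        warnings.warn(
            f"only {len(n_cells)} of {expected} region x hemisphere cells are "
            "populated; missing cells dropped and df adjusted"
        )
    return art_anova(
        cells,
        "amplitude",
        ["contrast", "region", "hemisphere"],
        "participant",
        compute_bfs=compute_bfs,
    )
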