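"""Group-level Bayes-factor mapping over searchlight beta maps.

For every hypothesis model the group stage computes, at each voxel:

* a *within-condition* map — right-tailed one-sample JZS Bayes t-test that
  the group's betas exceed zero, separately for aloud and silent reading
  (10 maps: 5 models x 2 conditions);
* a *between-condition* map — two-sided paired JZS Bayes t-test on the
  aloud - silent beta differences (5 maps).

Maps are thresholded at BF10 >= 3.0 ("moderate evidence"), split by the sign
of the group-mean difference, masked by the minuend condition's thresholded
within-condition map, and reduced to cluster tables (26-connected components,
minimum extent 20 voxels) reporting extent, mean / max BF10 and the
BF-weighted centre of gravity in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .bayes import jzs_bf_from_t
from .lexicon import CONDITIONS
from .rdm import MEASURES

DEFAULT_BF_FLOOR = 3.0
DEFAULT_MIN_EXTENT = 20

__all__ = [
    "GroupStack",
    "BFMap",
    "within_condition_map",
    "between_condition_map",
    "threshold_map",
    "directional_contrast",
    "extract_clusters",
    "GroupBayes",
    "GroupBayesResults",
]


@dataclass
class GroupStack:
    """Per-subject beta volumes for one (model, condition)."""

    data: np.ndarray  # (subject, x, y, z)
    subjects: tuple[str, ...]
    model: str
    condition: str
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.subjects):
            raise ValueError("one volume per subject required")
        if self.data.shape[0] < 2:
            raise ValueError("group analysis needs at least 2 subjects")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def complete_case(self) -> np.ndarray:
        """Voxels inside the mask where every subject has a finite value."""
        return self.mask & np.all(np.isfinite(self.data), axis=0)


@dataclass
class BFMap:
    """Voxelwise BF10 volume (NaN = missing / sub-threshold)."""

    values: np.ndarray
    tag: str  # e.g. "within-aloud", "between", "aloud>silent"
    model: str
    affine: np.ndarray
    thresholded: bool = False
    floor: float | None = None

    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def _stack_bf(data4d: np.ndarray, valid: np.ndarray, tail: str) -> np.ndarray:
    """Vectorised JZS BF over the valid voxels of a subject stack."""
    n = data4d.shape[0]
    out = np.full(data4d.shape[1:], np.nan)
    vox = data4d[:, valid]
    sd = vox.std(axis=0, ddof=1)
    good = sd > 0
    t = np.full(vox.shape[1], np.nan)
    t[good] = vox.mean(axis=0)[good] / (sd[good] / np.sqrt(n))
    out[valid] = jzs_bf_from_t(t, n, tail=tail)
    return out


def within_condition_map(stack: GroupStack) -> BFMap:
    """Right-tailed one-sample Bayes t-test that group betas exceed zero."""
    bf = _stack_bf(stack.data, stack.complete_case(), tail="right")
    return BFMap(bf, f"within-{stack.condition}", stack.model, stack.affine)


def between_condition_map(stack_a: GroupStack, stack_s: GroupStack) -> BFMap:
    """Two-sided paired Bayes t-test on aloud - silent differences."""
    if stack_a.subjects != stack_s.subjects:
        raise ValueError("paired test requires identical subject lists")
    if stack_a.data.shape != stack_s.data.shape:
        raise ValueError("stacks must share geometry")
    diff = stack_a.data - stack_s.data
    valid = stack_a.complete_case() & stack_s.complete_case()
    bf = _stack_bf(diff, valid, tail="two")
    return BFMap(bf, "between", stack_a.model, stack_a.affine)


def threshold_map(bfmap: BFMap, floor: float = DEFAULT_BF_FLOOR) -> BFMap:
    """Keep voxels with BF10 >= floor (inclusive); idempotent."""
    vals = bfmap.values.copy()
    vals[~(vals >= floor)] = np.nan
    return replace(bfmap, values=vals, thresholded=True, floor=floor)


def directional_contrast(
    between: BFMap,
    stack_a: GroupStack,
    stack_s: GroupStack,
    within_a: BFMap,
    within_s: BFMap,
) -> tuple[BFMap, BFMap]:
    """Split a thresholded between-condition map by direction, masked by the
    minuend condition's thresholded within-condition map.

    A voxel enters aloud>silent only if the group-mean aloud - silent
    difference is strictly positive *and* the within-aloud map is defined
    there (so the difference is not driven purely by negative betas in the
    subtrahend condition); symmetrically for silent>aloud.  The outputs are
    disjoint (exact ties enter neither).
    """
    for m in (between, within_a, within_s):
        if m.values.shape != stack_a.data.shape[1:]:
            raise ValueError("maps and stacks must share geometry")
        if not m.thresholded:
            raise ValueError(f"map {m.tag!r} must be thresholded first")
    if stack_a.data.shape != stack_s.data.shape:
        raise ValueError("stacks must share geometry")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels outside mask
        d = np.nanmean(stack_a.data, axis=0) - np.nanmean(stack_s.data, axis=0)
    base = between.defined()
    a_vals = np.where(base & (d > 0) & within_a.defined(), between.values, np.nan)
    s_vals = np.where(base & (d < 0) & within_s.defined(), between.values, np.nan)
    mk = lambda vals, tag: BFMap(
        vals, tag, between.model, between.affine, True, between.floor
    )
    return mk(a_vals, "aloud>silent"), mk(s_vals, "silent>aloud")


_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def extract_clusters(
    bfmap: BFMap,
    min_extent: int = DEFAULT_MIN_EXTENT,
    affine: np.ndarray | None = None,
    connectivity: np.ndarray = _CONNECTIVITY_26,
) -> pd.DataFrame:
    """Connected suprathreshold clusters with extent, BF summaries and COG.

    Components are 26-connected by default; those smaller than ``min_extent``
    voxels are dropped.  The centre of gravity is the BF-weighted centroid of
    the cluster, mapped to mm through the affine.  Rows are sorted by mean
    BF10, descending.
    """
    if not bfmap.thresholded:
        raise ValueError("cluster extraction expects a thresholded map")
    affine = bfmap.affine if affine is None else affine
    defined = bfmap.defined()
    labels, n_comp = ndimage.label(defined, structure=connectivity)
    rows = []
    for lab in range(1, n_comp + 1):
        sel = labels == lab
        extent = int(sel.sum())
        if extent < min_extent:
            continue
        vals = bfmap.values[sel]
        coords = np.argwhere(sel)
        cog_vox = (coords * vals[:, None]).sum(axis=0) / vals.sum()
        cog_mm = affine @ np.append(cog_vox, 1.0)
        rows.append(
            {
                "extent_voxels": extent,
                "mean_bf10": float(vals.mean()),
                "max_bf10": float(vals.max()),
                "x_mm": float(cog_mm[0]),
                "y_mm": float(cog_mm[1]),
                "z_mm": float(cog_mm[2]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["extent_voxels", "mean_bf10", "max_bf10", "x_mm", "y_mm", "z_mm"],
    )
    table = table.sort_values("mean_bf10", ascending=False, ignore_index=True)
    table.insert(0, "cluster_id", np.arange(1, len(table) + 1))
    return table


class GroupBayes:
    """Group Bayes-factor model over per-subject searchlight beta maps.

    Parameters
    ----------
    stacks : dict
        (model, condition) -> :class:`GroupStack`, for the five models and
        both conditions; all stacks must share subjects and geometry.
    bf_floor : float
        Evidence threshold (BF10, inclusive) applied to all maps.
    min_extent : int
        Minimum cluster extent in voxels.
    """

    def __init__(
        self,
        stacks: dict[tuple[str, str], GroupStack],
        bf_floor: float = DEFAULT_BF_FLOOR,
        min_extent: int = DEFAULT_MIN_EXTENT,
    ):
        self.stacks = stacks
        self.bf_floor = bf_floor
        self.min_extent = min_extent
        self.models = [m for m in MEASURES if (m, "aloud") in stacks] + sorted(
            {m for m, _ in stacks} - set(MEASURES)
        )
        ref = next(iter(stacks.values()))
        for st in stacks.values():
            if st.data.shape != ref.data.shape or st.subjects != ref.subjects:
                raise ValueError("all stacks must share subjects and geometry")

    @classmethod
    def from_searchlights(cls, results: list, mask=None, **kwargs) -> "GroupBayes":
        """Build stacks from per-subject :class:`SearchlightResults`."""
        by_key: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        affine = results[0].model.items.affine
        for res in results:
            for model, vol in res.beta_maps.items():
                by_key.setdefault((model, res.condition), {})[res.model.subject] = vol
        stacks = {}
        for (model, cond), sub_maps in by_key.items():
            subjects = tuple(sorted(sub_maps))
            stacks[(model, cond)] = GroupStack(
                np.stack([sub_maps[s] for s in subjects]),
                subjects,
                model,
                cond,
                affine,
                mask=mask,
            )
        return cls(stacks, **kwargs)

    def fit(self) -> "GroupBayesResults":
        within: dict[tuple[str, str], BFMap] = {}
        between: dict[str, BFMap] = {}
        contrasts: dict[str, tuple[BFMap, BFMap]] = {}
        for model in self.models:
            for cond in CONDITIONS:
                within[(model, cond)] = threshold_map(
                    within_condition_map(self.stacks[(model, cond)]), self.bf_floor
                )
            sa, ss = self.stacks[(model, "aloud")], self.stacks[(model, "silent")]
            btw = threshold_map(between_condition_map(sa, ss), self.bf_floor)
            between[model] = btw
            contrasts[model] = directional_contrast(
                btw, sa, ss, within[(model, "aloud")], within[(model, "silent")]
            )
        return GroupBayesResults(self, within, between, contrasts)


@dataclass
class GroupBayesResults:
    model: GroupBayes
    within: dict[tuple[str, str], BFMap]
    between: dict[str, BFMap]
    contrasts: dict[str, tuple[BFMap, BFMap]]

    def all_maps(self) -> list[BFMap]:
        return (
            list(self.within.values())
            + list(self.between.values())
            + [m for pair in self.contrasts.values() for m in pair]
        )

    def cluster_table(self, bfmap: BFMap) -> pd.DataFrame:
        return extract_clusters(bfmap, self.model.min_extent)

    def cluster_tables(self) -> dict[tuple[str, str], pd.DataFrame]:
        """Cluster tables for every map, keyed by (model, map tag)."""
        return {(m.model, m.tag): self.cluster_table(m) for m in self.all_maps()}

    def summary(self) -> str:
        n = next(iter(self.model.stacks.values())).n_subjects
        lines = [
            f"Group Bayes maps — {n} subjects, BF10 >= {self.model.bf_floor}, "
            f"min extent {self.model.min_extent} voxels"
        ]
        for (model, tag), table in self.cluster_tables().items():
            n_vox = int(np.isfinite(self._map_for(model, tag).values).sum())
            lines.append(
                f"  {model:<14s} {tag:<14s} suprathreshold voxels {n_vox:>6d}  "
                f"clusters {len(table)}"
            )
        return "\n".join(lines)

    def _map_for(self, model: str, tag: str) -> BFMap:
        for m in self.all_maps():
            if m.model == model and m.tag == tag:
                return m
        raise KeyError((model, tag))

    def save(self, directory) -> None:
        """Write BF10 NIfTIs and TSV cluster tables for every map."""
        from pathlib import Path

        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for m in self.all_maps():
            stem = f"{m.model}_{m.tag.replace('>', '_gt_')}"
            nib.save(
                nib.Nifti1Image(m.values.astype(np.float32), m.affine),
                directory / f"{stem}_bf10.nii.gz",
            )
            self.cluster_table(m).to_csv(
                directory / f"{stem}_clusters.tsv", sep="\t", index=False
            )
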