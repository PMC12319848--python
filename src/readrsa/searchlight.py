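"""Whole-volume searchlight RSA.

At every in-mask voxel, a spherical neighbourhood of item activation patterns
is turned into a neural representational dissimilarity matrix (1 - Pearson
over item pairs), vectorised, z-scored, and regressed on the five z-scored
hypothesis model vectors in a single GLM.  The five regression coefficients
(betas) are written back at the centre voxel, producing one whole-volume beta
map per hypothesis model, per subject and condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .glm import ItemPatternSet
from .rdm import MEASURES, ModelRDM, rdm_vectorize

__all__ = [
    "SearchlightSpec",
    "sphere_offsets",
    "neural_rdm",
    "rdm_regression",
    "SearchlightRSA",
    "SearchlightResults",
    "run_searchlight",
]


@dataclass(frozen=True)
class SearchlightSpec:
    """Sphere geometry: radius in voxel units and the minimum number of
    in-mask voxels a (mask-truncated) sphere must retain to be analysed."""

    radius: float = 3.0
    min_voxels: int = 10

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")


def sphere_offsets(radius: float) -> np.ndarray:
    """All integer offsets with Euclidean norm <= radius, lexicographic order.

    Radius 3 gives the 123-voxel sphere used as the default searchlight.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius))
    offs = [
        (x, y, z)
        for x, y, z in itertools.product(range(-r, r + 1), repeat=3)
        if x * x + y * y + z * z <= radius * radius
    ]
    return np.array(offs, dtype=int).reshape(-1, 3)


def neural_rdm(patterns: np.ndarray) -> np.ndarray:
    """Pairwise correlation distance (1 - Pearson) between item patterns."""
    p = np.asarray(patterns, dtype=float)
    if p.shape[0] < 3:
        raise ValueError("need at least 3 items for a neural RDM")
    if np.any(p.std(axis=1) == 0):
        raise ValueError("constant item pattern; correlation distance undefined")
    d = 1.0 - np.corrcoef(p)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance vector cannot be z-scored")
    return (v - v.mean()) / sd


def rdm_regression(neural_vec: np.ndarray, model_vecs: np.ndarray) -> np.ndarray:
    """OLS of the z-scored neural RDM vector on z-scored model vectors.

    ``model_vecs`` is (n_pairs, n_models); an intercept is included; the
    n_models coefficients are returned.  Raises on zero-variance input or a
    numerically collinear model set.
    """
    y = _zscore(np.asarray(neural_vec, dtype=float))
    M = np.asarray(model_vecs, dtype=float)
    if M.shape[0] != y.shape[0]:
        raise ValueError("neural and model vectors must have equal length")
    X = np.column_stack([np.apply_along_axis(_zscore, 0, M), np.ones(len(y))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("model RDM vectors are collinear")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta[: M.shape[1]]


class SearchlightRSA:
    """Searchlight RSA model for one subject and condition.

    Parameters
    ----------
    items : ItemPatternSet
        Mean-centered item patterns (item x in-mask voxel).
    models : dict of measure -> ModelRDM
        The five hypothesis models over the same items (any item order; they
        are reordered to match the pattern rows).
    spec : SearchlightSpec
    subject : str
    """

    def __init__(
        self,
        items: ItemPatternSet,
        models: dict[str, ModelRDM],
        spec: SearchlightSpec = SearchlightSpec(),
        subject: str = "sub-01",
    ):
        self.items = items
        self.spec = spec
        self.subject = subject
        self.model_names = [m for m in MEASURES if m in models] + [
            m for m in models if m not in MEASURES
        ]
        aligned = {}
        for name in self.model_names:
            rdm = models[name]
            if sorted(rdm.items) != sorted(items.items):
                raise ValueError(
                    f"model {name!r} items do not match the pattern item labels"
                )
            aligned[name] = rdm.reorder(list(items.items))
        self.models = aligned

    def fit(self) -> "SearchlightResults":
        betas = run_searchlight(
            self.items,
            self.models,
            spec=self.spec,
            model_order=self.model_names,
        )
        return SearchlightResults(self, betas)


@dataclass
class SearchlightResults:
    """Five beta volumes (NaN outside the mask / at invalid spheres)."""

    model: SearchlightRSA
    beta_maps: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def condition(self) -> str:
        return self.model.items.condition

    def summary(self) -> str:
        lines = [
            f"Searchlight RSA — subject {self.model.subject}, "
            f"condition {self.condition}, radius {self.model.spec.radius}"
        ]
        for name, vol in self.beta_maps.items():
            vals = vol[np.isfinite(vol)]
            lines.append(
                f"  {name:<14s} mean beta {vals.mean():+.4f}  "
                f"sd {vals.std(ddof=1):.4f}  voxels {vals.size}"
            )
        return "\n".join(lines)

    def save(self, directory, prefix: str | None = None) -> None:
        """Write each beta map as `{subject}_{condition}_{model}_beta.nii.gz`."""
        from pathlib import Path

        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prefix = prefix or f"{self.model.subject}_{self.condition}"
        for name, vol in self.beta_maps.items():
            img = nib.Nifti1Image(vol.astype(np.float32), self.model.items.affine)
            nib.save(img, directory / f"{prefix}_{name}_beta.nii.gz")


def run_searchlight(
    items: ItemPatternSet,
    models: dict[str, ModelRDM],
    spec: SearchlightSpec = SearchlightSpec(),
    model_order: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Compute the beta maps for one item pattern set.

    For each in-mask voxel: intersect the sphere with the mask, build the
    neural RDM from the member-voxel patterns, vectorise, and regress on the
    model vectors.  Invalid spheres (too small, or containing a constant item
    pattern) receive NaN in all maps.
    """
    mask = items.mask
    names = model_order or [m for m in MEASURES if m in models] + [
        m for m in models if m not in MEASURES
    ]
    for name in names:
        if tuple(models[name].items) != tuple(items.items):
            raise ValueError(f"model {name!r} item order does not match patterns")
    X = np.column_stack([_zscore(models[m].vectorize()) for m in names])
    X = np.column_stack([X, np.ones(X.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("model RDM vectors are collinear")
    pinv = np.linalg.pinv(X)

    offsets = sphere_offsets(spec.radius).astype(np.int64)
    index_vol = np.full(mask.shape, -1, dtype=np.int64)
    coords = np.argwhere(mask)
    index_vol[mask] = np.arange(len(coords))
    pats = items.patterns
    shape = np.array(mask.shape)
    maps = {m: np.full(mask.shape, np.nan) for m in names}
    tri_i, tri_j = np.tril_indices(pats.shape[0], k=-1)

    for center in coords:
        pos = center[None, :] + offsets
        ok = np.all((pos >= 0) & (pos < shape[None, :]), axis=1)
        member = index_vol[pos[ok, 0], pos[ok, 1], pos[ok, 2]]
        member = member[member >= 0]
        if member.size < spec.min_voxels:
            continue
        local = pats[:, member]
        sd = local.std(axis=1)
        if np.any(sd == 0):
            continue
        d = 1.0 - np.corrcoef(local)
        vec = d[tri_i, tri_j]
        vsd = vec.std(ddof=1)
        if vsd == 0:
            continue
        beta = pinv @ ((vec - vec.mean()) / vsd)
        for k, name in enumerate(names):
            maps[name][tuple(center)] = beta[k]
    return maps
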