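"""Synthetic word-reading studies with planted representational geometry.

The generator emulates the study design the analysis pipeline targets:
30 word stimuli (6-10 letters), randomly split 15/15 into aloud and silent
reading per subject, presented once per run in each of 4 runs at a fixed
6 s SOA, acquired as 100 volumes per run at TR 1.8 s.  Words carry synthetic
transcriptions, embeddings and per-speaker MFCC sequences so that all five
hypothesis models can be built from the lexicon alone.

"Planting" writes known representational geometry into a region of the
ground-truth item patterns: prototype item coordinates are obtained by
classical multidimensional scaling of the target model RDM, embedded into
voxel space by a random linear map, and mixed with noise patterns; the mixing
weight is calibrated by bisection until the neural RDM of the patterns
correlates with the vectorised model at the requested level.  BOLD runs are
then synthesised as design x patterns plus (optionally AR(1)) Gaussian noise,
so the whole pipeline — LSA, averaging, centering, searchlight, group maps —
can be validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import (
    DEFAULT_DURATION,
    DEFAULT_SOA,
    DEFAULT_TR,
    BoldRun,
    ItemPatternSet,
    build_design_matrix,
    gamma_hrf,
)
from .lexicon import CONDITIONS, Lexicon, WordEntry, load_phoneme_features
from .rdm import ModelRDM, rdm_vectorize
from .stimuli import RenderConfig, build_model_rdms, orthographic_rdm

_VOWELS = "aeiou"
_CONSONANTS = "bdfghklmnprstvwz"
_LETTER_TO_PHONEME = {
    "a": "a", "b": "b", "c": "k", "d": "d", "e": "e", "f": "f", "g": "g",
    "h": "h", "i": "i", "j": "dZ", "k": "k", "l": "l", "m": "m", "n": "n",
    "o": "o", "p": "p", "q": "k", "r": "r", "s": "s", "t": "t", "u": "u",
    "v": "v", "w": "w", "x": "s", "y": "j", "z": "z",
}

DEFAULT_SHAPE = (24, 24, 16)
DEFAULT_N_SUBJECTS = 26
DEFAULT_N_RUNS = 4
DEFAULT_N_WORDS = 30
DEFAULT_VOLS_PER_RUN = 100
DEFAULT_NOISE_SCALE = 0.5

__all__ = [
    "PlantSpec",
    "SyntheticDataset",
    "SubjectData",
    "generate_lexicon",
    "allocate_conditions",
    "plant_item_patterns",
    "simulate_subject_bold",
    "make_events",
    "ellipsoid_mask",
    "make_dataset",
]


def generate_lexicon(
    n: int = DEFAULT_N_WORDS,
    seed: int | np.random.SeedSequence = 0,
    embedding_dim: int = 50,
    speakers: tuple[str, ...] = ("spk-a", "spk-b"),
    n_mfcc: int = 12,
) -> Lexicon:
    """Generate ``n`` unique pronounceable words with all stimulus attributes.

    Words are built from consonant-vowel syllables (lengths 6-10 letters);
    transcriptions map letters onto the bundled toy phoneme inventory;
    embeddings are iid standard normal; MFCC sequences are smooth per-word
    prototype trajectories perturbed per speaker.
    """
    if n < 2:
        raise ValueError("need at least 2 words")
    rng = np.random.default_rng(seed)
    words: list[str] = []
    seen = set()
    attempts = 0
    while len(words) < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError(f"cannot generate {n} unique words")
        target = int(rng.integers(6, 11))
        w = ""
        while len(w) < target:
            w += rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        w = w[:target]
        if w[-1] in _VOWELS or rng.random() < 0.5:
            pass  # keep as is; roughly half the words end on a consonant cut
        if w not in seen:
            seen.add(w)
            words.append(w)
    entries = []
    for w in words:
        transcription = tuple(_LETTER_TO_PHONEME[ch] for ch in w)
        embedding = rng.standard_normal(embedding_dim)
        proto_len = int(rng.integers(24, 40))
        # smooth per-word acoustic trajectory: integrated noise, mild decay
        steps = rng.standard_normal((proto_len, n_mfcc))
        proto = np.cumsum(steps, axis=0) / np.sqrt(np.arange(1, proto_len + 1))[:, None]
        mfcc = {}
        for spk in speakers:
            jitter = 0.35 * rng.standard_normal((proto_len, n_mfcc))
            offset = 0.5 * rng.standard_normal((1, n_mfcc))
            mfcc[spk] = proto + offset + jitter
        entries.append(
            WordEntry(
                text=w,
                transcription=transcription,
                embedding=embedding,
                mfcc_by_speaker=mfcc,
            )
        )
    return Lexicon(entries)


def allocate_conditions(
    lexicon: Lexicon, seed: int | np.random.SeedSequence = 0
) -> dict[str, str]:
    """Uniformly random half/half aloud-silent split of the word list."""
    words = lexicon.words
    if len(words) % 2:
        raise ValueError("condition allocation needs an even word count")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(words))
    half = len(words) // 2
    out = {}
    for rank, idx in enumerate(order):
        out[words[idx]] = "aloud" if rank < half else "silent"
    return out


# ------------------------------------------------------------------ planting


def _mds_coordinates(rdm: np.ndarray) -> np.ndarray:
    """Classical MDS of sqrt(RDM), so squared prototype distances track the RDM."""
    d = np.sqrt(np.asarray(rdm, float))
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    keep = vals > max(vals.max(), 1e-12) * 1e-9
    return vecs[:, keep] * np.sqrt(vals[keep])


def _row_standardize(p: np.ndarray) -> np.ndarray:
    p = p - p.mean(axis=1, keepdims=True)
    return p / p.std(axis=1, keepdims=True)


def _neural_model_r(patterns: np.ndarray, model_vec: np.ndarray) -> float:
    d = 1.0 - np.corrcoef(patterns)
    i, j = np.tril_indices(d.shape[0], k=-1)
    return float(np.corrcoef(d[i, j], model_vec)[0, 1])


def plant_item_patterns(
    model: ModelRDM,
    n_voxels: int,
    rho_target: float,
    seed: int | np.random.SeedSequence = 0,
    n_replicates: int = 20,
    tol: float = 0.05,
    max_iter: int = 40,
) -> tuple[np.ndarray, float]:
    """Item x voxel patterns whose neural RDM correlates with ``model``.

    The signal component embeds MDS prototypes of the model RDM into voxel
    space through a random linear map; mixing weight w between signal and
    iid noise is calibrated by bisection so that the mean (over
    ``n_replicates`` random replicates) Pearson correlation between the
    patterns' neural RDM and the vectorised model hits ``rho_target``.  The
    replicate whose own measured correlation is closest to the target is
    returned, together with its achieved correlation.
    """
    if not 0.0 <= rho_target < 1.0:
        raise ValueError("rho_target must lie in [0, 1)")
    if n_voxels < 20:
        raise ValueError("need at least 20 voxels to plant a geometry")
    rng = np.random.default_rng(seed)
    n_items = model.n_items
    model_vec = rdm_vectorize(model.matrix)
    coords = _mds_coordinates(model.matrix)

    replicates = []
    for _ in range(n_replicates):
        mapping = rng.standard_normal((coords.shape[1], n_voxels)) / np.sqrt(n_voxels)
        signal = _row_standardize(coords @ mapping)
        noise = _row_standardize(rng.standard_normal((n_items, n_voxels)))
        replicates.append((signal, noise))

    def mix(w: float, rep) -> np.ndarray:
        signal, noise = rep
        return w * signal + (1.0 - w) * noise

    def mean_r(w: float) -> float:
        return float(np.mean([_neural_model_r(mix(w, rep), model_vec) for rep in replicates]))

    if rho_target == 0.0:
        w_star = 0.0
    else:
        lo, hi = 0.0, 1.0
        if mean_r(1.0) < rho_target - tol:
            raise RuntimeError(
                f"cannot reach rho={rho_target}: pure signal achieves r={mean_r(1.0):.3f}"
            )
        for _ in range(max_iter):
            mid = (lo + hi) / 2.0
            if mean_r(mid) < rho_target:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-4:
                break
        w_star = (lo + hi) / 2.0
        achieved_mean = mean_r(w_star)
        if abs(achieved_mean - rho_target) > tol:
            raise RuntimeError(
                f"calibration failed: target {rho_target}, achieved {achieved_mean:.3f}"
            )

    measured = [_neural_model_r(mix(w_star, rep), model_vec) for rep in replicates]
    if rho_target == 0.0:
        best = 0
    else:
        best = int(np.argmin(np.abs(np.asarray(measured) - rho_target)))
    return mix(w_star, replicates[best]), float(measured[best])


@dataclass
class PlantSpec:
    """Where and what to plant: a region, a model tag, a target correlation,
    and which condition(s) carry the geometry."""

    region: np.ndarray  # 3D boolean, inside the brain mask
    model: str = "articulatory"
    rho_target: float = 0.5
    conditions: tuple[str, ...] = ("aloud",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_target < 1.0:
            raise ValueError("rho_target must lie in [0, 1)")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}")


# ---------------------------------------------------------------------- BOLD


def make_events(
    words: list[str],
    conditions: dict[str, str],
    seed: int | np.random.SeedSequence = 0,
    soa: float = DEFAULT_SOA,
    duration: float = DEFAULT_DURATION,
) -> pd.DataFrame:
    """One run's events: every word once, random order, fixed SOA."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(words))
    rows = [
        {
            "onset": i * soa,
            "duration": duration,
            "word": words[k],
            "condition": conditions[words[k]],
        }
        for i, k in enumerate(order)
    ]
    return pd.DataFrame(rows)


def simulate_subject_bold(
    item_patterns: dict[str, ItemPatternSet],
    events_per_run: list[pd.DataFrame],
    tr: float = DEFAULT_TR,
    n_vols: int = DEFAULT_VOLS_PER_RUN,
    hrf: np.ndarray | None = None,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    ar_phi: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> list[BoldRun]:
    """Synthesise one subject's runs as design x ground-truth patterns + noise.

    ``item_patterns`` maps condition -> ground-truth :class:`ItemPatternSet`
    over the full mask.  Noise is white Gaussian with standard deviation
    ``noise_scale``; with ``ar_phi`` > 0 it follows a stationary AR(1)
    process with that coefficient.
    """
    rng = np.random.default_rng(seed)
    if hrf is None:
        hrf = gamma_hrf()
    ref = next(iter(item_patterns.values()))
    mask, affine = ref.mask, ref.affine
    n_vox = int(mask.sum())
    lookup = {
        (cond, word): ips.patterns[ips.items.index(word)]
        for cond, ips in item_patterns.items()
        for word in ips.items
    }
    runs = []
    for run_idx, events in enumerate(events_per_run):
        design = build_design_matrix(events, n_vols, tr, hrf=hrf)
        amplitudes = np.stack(
            [
                lookup[(row.condition, row.word)]
                for row in events.itertuples(index=False)
            ]
        )
        signal = design.matrix[:, : design.n_trials] @ amplitudes
        eps = rng.standard_normal((n_vols, n_vox))
        if ar_phi:
            for t in range(1, n_vols):
                eps[t] = ar_phi * eps[t - 1] + np.sqrt(1 - ar_phi**2) * eps[t]
        data = np.zeros(mask.shape + (n_vols,), dtype=np.float32)
        data[mask] = (signal + noise_scale * eps).T
        runs.append(
            BoldRun(data, tr, mask, affine, run_id=f"run-{run_idx + 1:02d}")
        )
    return runs


def ellipsoid_mask(shape: tuple[int, int, int] = DEFAULT_SHAPE) -> np.ndarray:
    """Ellipsoidal 'brain' mask inscribed in the volume (about 45% of voxels)."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [s / 2.0 - 0.5 for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


# ------------------------------------------------------------------- dataset


@dataclass
class SubjectData:
    subject: str
    allocation: dict[str, str]
    model_rdms: dict[str, dict[str, ModelRDM]]  # condition -> measure -> RDM
    true_patterns: dict[str, ItemPatternSet]  # condition -> ground truth
    events: list[pd.DataFrame]
    runs: list[BoldRun]
    achieved_rho: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    """A complete synthetic study plus its ground truth."""

    lexicon: Lexicon
    subjects: list[SubjectData]
    mask: np.ndarray
    affine: np.ndarray
    tr: float
    plant_specs: list[PlantSpec]
    seed: int
    manifest: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _exemplar_rdms(lexicon: Lexicon, cfg: RenderConfig) -> dict[str, ModelRDM]:
    ft = load_phoneme_features()
    return build_model_rdms(lexicon, ft, cfg=cfg)


def _condition_rdms(
    lexicon: Lexicon,
    allocation: dict[str, str],
    exemplar: dict[str, ModelRDM],
    condition: str,
) -> dict[str, ModelRDM]:
    """Condition-specific 15-item models.

    Visual, phonological, semantic and articulatory dissimilarities are
    pairwise properties, so the condition model is the exemplar submatrix;
    the orthographic model is recomputed because its bigram vocabulary is
    defined by the word set entering the model.
    """
    words = [w for w in lexicon.words if allocation[w] == condition]
    out = {}
    for measure, rdm in exemplar.items():
        if measure == "orthographic":
            out[measure] = orthographic_rdm(words)
        else:
            idx = [rdm.items.index(w) for w in words]
            out[measure] = ModelRDM(
                tuple(words), rdm.matrix[np.ix_(idx, idx)], measure
            )
    return out


def make_dataset(
    n_subjects: int = DEFAULT_N_SUBJECTS,
    plant_specs: list[PlantSpec] | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    mask: np.ndarray | None = None,
    n_runs: int = DEFAULT_N_RUNS,
    n_words: int = DEFAULT_N_WORDS,
    tr: float = DEFAULT_TR,
    n_vols: int = DEFAULT_VOLS_PER_RUN,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    ar_phi: float = 0.0,
    pattern_scale: float = 1.0,
    render_cfg: RenderConfig = RenderConfig(),
    generate_bold: bool = True,
) -> SyntheticDataset:
    """Generate a full synthetic study.

    One master seed fans out deterministically through
    ``numpy.random.SeedSequence(seed).spawn``: child 0 seeds the lexicon,
    then each subject receives one child whose own spawn covers allocation,
    planting (per spec and condition), events and BOLD noise, in that order.
    The spawning order is recorded in the manifest.
    """
    plant_specs = list(plant_specs or [])
    ss = np.random.SeedSequence(seed)
    lex_ss, *subject_ss = ss.spawn(1 + n_subjects)
    lexicon = generate_lexicon(n_words, seed=lex_ss)
    if mask is None:
        mask = ellipsoid_mask(shape)
    affine = np.diag([3.75, 3.75, 3.75, 1.0])  # functional voxel size in mm
    n_vox = int(mask.sum())
    region_cols = [np.flatnonzero(spec.region[mask]) for spec in plant_specs]
    for spec, cols in zip(plant_specs, region_cols):
        if spec.region.shape != mask.shape:
            raise ValueError("plant region must share the mask's shape")
        if int(spec.region.sum()) != len(cols):
            raise ValueError("plant region must lie inside the brain mask")

    exemplar = _exemplar_rdms(lexicon, render_cfg)
    hrf = gamma_hrf()
    subjects = []
    for s_idx, sub_ss in enumerate(subject_ss):
        alloc_ss, plant_ss, events_ss, bold_ss = sub_ss.spawn(4)
        allocation = allocate_conditions(lexicon, seed=alloc_ss)
        sub_lex = lexicon.with_conditions(allocation)
        rdms = {
            cond: _condition_rdms(lexicon, allocation, exemplar, cond)
            for cond in CONDITIONS
        }
        pattern_rng = np.random.default_rng(plant_ss)
        plant_children = plant_ss.spawn(max(1, len(plant_specs)) * len(CONDITIONS))
        true_patterns: dict[str, ItemPatternSet] = {}
        achieved: dict[tuple[str, str], float] = {}
        for c_idx, cond in enumerate(CONDITIONS):
            words = [w for w in lexicon.words if allocation[w] == cond]
            pats = pattern_scale * _row_standardize(
                pattern_rng.standard_normal((len(words), n_vox))
            )
            for p_idx, spec in enumerate(plant_specs):
                if cond not in spec.conditions:
                    continue
                cols = region_cols[p_idx]
                planted, rho = plant_item_patterns(
                    rdms[cond][spec.model],
                    len(cols),
                    spec.rho_target,
                    seed=plant_children[p_idx * len(CONDITIONS) + c_idx],
                )
                pats[:, cols] = pattern_scale * planted
                achieved[(spec.model, cond)] = rho
            true_patterns[cond] = ItemPatternSet(
                pats, tuple(words), cond, mask, affine, centered=False
            )
        events = [
            make_events(lexicon.words, allocation, seed=es)
            for es in events_ss.spawn(n_runs)
        ]
        runs = (
            simulate_subject_bold(
                true_patterns,
                events,
                tr=tr,
                n_vols=n_vols,
                hrf=hrf,
                noise_scale=noise_scale,
                ar_phi=ar_phi,
                seed=bold_ss,
            )
            if generate_bold
            else []
        )
        subjects.append(
            SubjectData(
                subject=f"sub-{s_idx + 1:02d}",
                allocation=allocation,
                model_rdms=rdms,
                true_patterns=true_patterns,
                events=events,
                runs=runs,
                achieved_rho=achieved,
            )
        )
    manifest = {
        "seed": seed,
        "spawn_order": "lexicon, then per subject: (allocation, planting, events, bold)",
        "n_subjects": n_subjects,
        "n_runs": n_runs,
        "n_words": n_words,
        "tr": tr,
        "n_vols": n_vols,
        "noise_scale": noise_scale,
        "ar_phi": ar_phi,
        "pattern_scale": pattern_scale,
        "shape": list(mask.shape),
        "plants": [
            {
                "model": spec.model,
                "rho_target": spec.rho_target,
                "conditions": list(spec.conditions),
                "region_voxels": int(spec.region.sum()),
            }
            for spec in plant_specs
        ],
        "achieved_rho": {
            f"{sub.subject}:{model}:{cond}": rho
            for sub in subjects
            for (model, cond), rho in sub.achieved_rho.items()
        },
    }
    return SyntheticDataset(
        lexicon=lexicon,
        subjects=subjects,
        mask=mask,
        affine=affine,
        tr=tr,
        plant_specs=plant_specs,
        seed=seed,
        manifest=manifest,
    )
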