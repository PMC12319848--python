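"""End-to-end drivers: from BOLD runs to group Bayes maps.

These helpers chain the package's stages in the order the analysis defines:
per-run LSA trial GLMs -> item averaging across runs -> condition-mean
subtraction -> per-condition searchlight RSA -> group Bayes-factor mapping.
They exist so that synthetic studies (and the command line) can run the whole
pipeline with one call; each stage remains usable on its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glm import (
    BoldRun,
    TrialGLM,
    average_item_patterns,
    subtract_condition_mean,
)
from .group import GroupBayes, GroupBayesResults
from .lexicon import CONDITIONS
from .rdm import ModelRDM
from .searchlight import SearchlightRSA, SearchlightResults, SearchlightSpec
from .simulate import SyntheticDataset

__all__ = ["estimate_item_patterns", "analyze_subject", "analyze_dataset"]


def estimate_item_patterns(
    runs: list[BoldRun],
    events_per_run: list[pd.DataFrame],
    item_order: dict[str, list[str]] | None = None,
    detrend: bool = False,
):
    """LSA-fit every run, average item repetitions, and mean-center.

    Returns condition -> centered :class:`ItemPatternSet`.  ``item_order``
    optionally fixes per-condition item ordering (e.g. to match model RDMs).
    """
    trial_sets = [
        TrialGLM(run, events, detrend=detrend).fit().trial_patterns
        for run, events in zip(runs, events_per_run)
    ]
    out = {}
    for cond in CONDITIONS:
        order = item_order.get(cond) if item_order else None
        items = average_item_patterns(
            trial_sets, cond, item_order=order, n_reps=len(runs)
        )
        out[cond] = subtract_condition_mean(items)
    return out


def analyze_subject(
    runs: list[BoldRun],
    events_per_run: list[pd.DataFrame],
    model_rdms: dict[str, dict[str, ModelRDM]],
    spec: SearchlightSpec = SearchlightSpec(),
    subject: str = "sub-01",
) -> list[SearchlightResults]:
    """Full single-subject analysis: two searchlight results (one per condition)."""
    item_order = {c: list(next(iter(model_rdms[c].values())).items) for c in model_rdms}
    patterns = estimate_item_patterns(runs, events_per_run, item_order=item_order)
    return [
        SearchlightRSA(patterns[c], model_rdms[c], spec=spec, subject=subject).fit()
        for c in CONDITIONS
    ]


def analyze_dataset(
    dataset: SyntheticDataset,
    spec: SearchlightSpec = SearchlightSpec(),
    bf_floor: float = 3.0,
    min_extent: int = 20,
    use_true_patterns: bool = False,
    verbose: bool = False,
) -> GroupBayesResults:
    """Run the whole pipeline on a synthetic study.

    With ``use_true_patterns`` the LSA stage is bypassed and the searchlight
    consumes the stored ground-truth patterns (mean-centered), which isolates
    the searchlight and group stages from estimation noise.
    """
    all_results: list[SearchlightResults] = []
    for sub in dataset.subjects:
        if use_true_patterns:
            patterns = {
                c: subtract_condition_mean(sub.true_patterns[c]) for c in CONDITIONS
            }
            results = [
                SearchlightRSA(
                    patterns[c], sub.model_rdms[c], spec=spec, subject=sub.subject
                ).fit()
                for c in CONDITIONS
            ]
        else:
            results = analyze_subject(
                sub.runs, sub.events, sub.model_rdms, spec=spec, subject=sub.subject
            )
        all_results.extend(results)
        if verbose:
            print(f"searchlight done: {sub.subject}")
    group = GroupBayes.from_searchlights(
        all_results, mask=dataset.mask, bf_floor=bf_floor, min_extent=min_extent
    )
    return group.fit()
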