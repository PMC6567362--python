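"""Matching-pattern-paradigm (MPP) templates.

An MPP is a single reference sequence per motion category against which
candidate segments are matched by total warping cost.  Two construction
policies are supported:

averaged
    Every training sample of a category is equalized to a common length,
    min-max normalized onto [0, 1], and the template is the pointwise mean.
    Either equalizer (DFT interpolation or convolution) may be used.

random
    One raw training sample per category is drawn uniformly; no averaging,
    no equalization.

An optional automatic rejection pass drops, per category, the samples whose
warping cost against the provisional averaged template exceeds the 90th
percentile, then re-averages once — a reproducible stand-in for hand-curated
removal of degraded recordings.

``consensus_recall`` scores a template set by classifying the very samples
that generated it and reporting the fraction recovered correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtw import dtw_cost
from .equalize import equalize, normalize_unit_interval
from .sequence import MotionSequence

__all__ = ["TemplateSet", "build_averaged_mpps", "select_random_mpps",
           "consensus_recall"]


@dataclass
class TemplateSet:
    """Per-category matching pattern paradigms.

    Attributes
    ----------
    templates : dict
        Maps category label to a 1-D template array.
    method : str
        'averaged_dft', 'averaged_conv' or 'random'.
    template_length : int or None
        Common length M of averaged templates (None for raw random picks).
    source_count : dict
        Number of training samples behind each template.
    """

    templates: dict
    method: str
    template_length: int = None
    source_count: dict = field(default_factory=dict)

    @property
    def labels(self):
        return sorted(self.templates)

    def __len__(self):
        return len(self.templates)


def _group_by_label(samples):
    groups: dict = {}
    for s in samples:
        if s.label is None:
            raise ValueError("unlabeled sample in template training data")
        groups.setdefault(s.label, []).append(s)
    if not groups:
        raise ValueError("no training samples supplied")
    return groups


def build_averaged_mpps(samples, target_length=None, method="dft",
                        normalize=True, reject_outliers=False) -> TemplateSet:
    """Averaged MPPs: equalize -> normalize -> pointwise mean, per category.

    Parameters
    ----------
    samples : iterable of MotionSequence
        Labeled training sequences; every category needs at least one.
    target_length : int, optional
        Common template length M; defaults to the longest sample (both
        equalizers only upsample).
    method : {'dft', 'conv'}
        Which equalizer stretches the samples to length M.
    normalize : bool, default True
        Min-max normalize each equalized sample before averaging.
    reject_outliers : bool, default False
        Drop samples above the 90th percentile of warping cost to the
        provisional template, then re-average once.
    """
    samples = list(samples)
    groups = _group_by_label(samples)
    if target_length is None:
        target_length = max(len(s) for s in samples)
    m = int(target_length)

    def _mean_template(seqs):
        eq = np.vstack([equalize(s.samples, m, method=method,
                                 normalize=normalize) for s in seqs])
        return eq.mean(axis=0), eq

    templates, counts = {}, {}
    for label, seqs in groups.items():
        tmpl, eq = _mean_template(seqs)
        if reject_outliers and len(seqs) > 1:
            costs = np.array([dtw_cost(row, tmpl) for row in eq])
            keep = costs <= np.percentile(costs, 90)
            kept = [s for s, k in zip(seqs, keep) if k]
            if kept and len(kept) < len(seqs):
                tmpl, _ = _mean_template(kept)
                seqs = kept
        templates[label] = tmpl
        counts[label] = len(seqs)
    return TemplateSet(templates=templates,
                       method=f"averaged_{'conv' if method.startswith('conv') else 'dft'}",
                       template_length=m, source_count=counts)


def select_random_mpps(samples, seed=None) -> TemplateSet:
    """One uniformly chosen raw sample per category; reproducible under seed."""
    groups = _group_by_label(samples)
    rng = np.random.default_rng(seed)
    templates, counts = {}, {}
    for label in sorted(groups, key=str):
        seqs = groups[label]
        pick = seqs[int(rng.integers(len(seqs)))]
        templates[label] = np.asarray(pick.samples, dtype=float).copy()
        counts[label] = len(seqs)
    return TemplateSet(templates=templates, method="random",
                       template_length=None, source_count=counts)


def consensus_recall(template_set: TemplateSet, samples,
                     normalize_queries=None) -> float:
    """Fraction of generating samples the template set labels correctly.

    Each sample is matched by minimum total warping cost against every
    template (ties broken toward the lowest category code).  By default
    queries are min-max normalized when the templates are averaged (which
    are built from normalized sources) and left raw when the templates are
    raw random picks, so both sides always share an amplitude scale.
    """
    from .classify import classify_sequence  # circular at import time

    samples = list(samples)
    if not samples:
        raise ValueError("no samples to score")
    for s in samples:
        if s.label not in template_set.templates:
            raise KeyError(f"sample label {s.label!r} has no template")
    if normalize_queries is None:
        normalize_queries = template_set.method.startswith("averaged")
    correct = 0
    for s in samples:
        q = normalize_unit_interval(s.samples) if normalize_queries else s.samples
        if classify_sequence(q, template_set) == s.label:
            correct += 1
    return correct / len(samples)
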