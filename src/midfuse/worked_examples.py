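"""Reference evaluation records from a published four-instrument
Fritillaria authentication study.

The original study reports, for each species-identification model, the
list of misclassified samples (out of 20 per species class). These
printed records are small enough to re-evaluate exactly: rebuilding the
confusion matrix from each list and running :mod:`midfuse.evaluation`
on it reproduces the published accuracies, which makes the lists useful
worked examples for the metric definitions.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics

SPECIES = ("FU", "FP", "FD", "FUS")
N_PER_CLASS = 20

# Misclassification records of the six species models (true -> predicted
# -> count). Electronic-tongue destinations were not itemized in the
# published record; only the per-class error totals are known, so each
# class's errors are routed to a single placeholder destination — the
# accuracy is unaffected by the destination choice.
MISCLASSIFIED: dict[str, dict[tuple[str, str], int]] = {
    "electronic_nose": {
        ("FU", "FD"): 3, ("FP", "FD"): 3, ("FP", "FUS"): 1, ("FD", "FP"): 1,
        ("FUS", "FU"): 1, ("FUS", "FP"): 2, ("FUS", "FD"): 1,
    },
    "electronic_tongue": {
        ("FU", "FP"): 7, ("FP", "FU"): 6, ("FD", "FUS"): 5, ("FUS", "FD"): 5,
    },
    "electronic_eye": {
        ("FD", "FUS"): 1, ("FUS", "FD"): 1,
    },
    "nir": {
        ("FUS", "FU"): 1, ("FUS", "FD"): 1,
    },
    # sample-level records: S2 (FU)->FD, S45 (FD)->FP, S43 (FUS)->FP,
    # S79 (FUS)->FU
    "three_source_fusion": {
        ("FU", "FD"): 1, ("FD", "FP"): 1, ("FUS", "FP"): 1, ("FUS", "FU"): 1,
    },
    # S43 (FUS)->FP, S79 (FUS)->FU
    "four_source_fusion": {
        ("FUS", "FP"): 1, ("FUS", "FU"): 1,
    },
}


def species_labels(model: str) -> tuple[list[str], list[str]]:
    """Expand a misclassification record to per-sample true/predicted labels."""
    record = MISCLASSIFIED[model]
    true: list[str] = []
    pred: list[str] = []
    for cls in SPECIES:
        errors = [(dst, k) for (src, dst), k in record.items() if src == cls]
        n_wrong = sum(k for _, k in errors)
        if n_wrong > N_PER_CLASS:
            raise ValueError(f"{model}: more errors than samples in class {cls}")
        true += [cls] * N_PER_CLASS
        pred += [cls] * (N_PER_CLASS - n_wrong)
        for dst, k in errors:
            pred += [dst] * k
    return true, pred


def species_confusion(model: str) -> ConfusionMatrix:
    true, pred = species_labels(model)
    return confusion(true, pred, class_order=SPECIES)


def species_metrics(model: str) -> MetricsReport:
    return metrics(species_confusion(model))


def all_species_accuracies() -> dict[str, float]:
    """Accuracy of every recorded species model, as a percentage."""
    return {model: 100.0 * species_metrics(model).accuracy
            for model in MISCLASSIFIED}
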