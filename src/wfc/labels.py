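"""Ground-truth label taxonomy and derived binary partitions.

Images carry one of five labels: ``normal`` or an abnormality label naming
the lesion type (calcification or mass) and its pathology (benign or
malignant).  Classifiers never see the five-way label directly; they train
on derived binary partitions: *any* abnormality vs normal, or one lesion
type vs everything else (used by tuned classifiers).
"""

from __future__ import annotations

import numpy as np

LABELS = ("normal", "calc_benign", "calc_malignant", "mass_benign", "mass_malignant")

#: Valid tuned-target partitions.
TARGETS = ("any", "calcification", "mass")


def is_suspicious(label: str) -> bool:
    """True for any abnormality label."""
    return label != "normal"


def is_calcification(label: str) -> bool:
    return label.startswith("calc_")


def is_mass(label: str) -> bool:
    return label.startswith("mass_")


def validate_label(label: str) -> str:
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    return label


def target_vector(labels, target: str = "any") -> np.ndarray:
    """Binary positive-class indicator for a label partition.

    Parameters
    ----------
    labels : sequence of str
        Five-way ground-truth labels.
    target : {'any', 'calcification', 'mass'}
        ``'any'`` marks every abnormality positive; the lesion-specific
        targets mark only that lesion type positive (all other images,
        including the other abnormality, count as negatives).
    """
    if target == "any":
        pred = is_suspicious
    elif target == "calcification":
        pred = is_calcification
    elif target == "mass":
        pred = is_mass
    else:
        raise ValueError(f"unknown target {target!r}; expected one of {TARGETS}")
    labels = [validate_label(l) for l in labels]
    return np.array([pred(l) for l in labels], dtype=bool)
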