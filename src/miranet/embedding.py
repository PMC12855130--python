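"""Instruction-space embedding analysis.

The claim under test: after unified training, the ARC attention vectors of
samples from different degradation tasks occupy well-separated regions of the
simplex, whereas at initialization they overlap.  Instead of a qualitative
2-D projection, separation is quantified by the mean silhouette score of the
task labelling in alpha-space, plus the accuracy of identifying the task from
the argmax attention atom under the best atom-to-task assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import silhouette_score as _sk_silhouette

from .degradations import PairedSample
from .image import ValidationError
from .model import MiraNet


@dataclass(frozen=True)
class EmbeddingSet:
    """Per-sample attention vectors with their task labels."""

    vectors: np.ndarray  # (n_samples, n_atoms)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != len(self.labels):
            raise ValidationError("vectors and labels must have equal length")
        if np.any(v < -1e-9) or np.any(np.abs(v.sum(axis=1) - 1.0) > 1e-6):
            raise ValidationError("every embedding must lie on the simplex")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class SeparationReport:
    silhouette_before: float
    silhouette_after: float
    argmax_accuracy: float
    atom_assignment: dict[int, str]


def extract_embeddings(model: MiraNet, samples: Sequence[PairedSample]
                       ) -> EmbeddingSet:
    """ARC attention of each low-quality input, labelled by its task."""
    if len(samples) == 0:
        raise ValidationError("samples must be non-empty")
    vectors = np.stack([model.instruction_state(s.low_quality).attention
                        for s in samples])
    labels = tuple(s.degradation_label for s in samples)
    return EmbeddingSet(vectors=vectors, labels=labels)


def silhouette_score(embeddings: EmbeddingSet) -> float:
    """Mean Euclidean silhouette of the task labelling, in [-1, 1].

    All-identical points score 0 by contract (separation is undefined there).
    """
    labels = np.asarray(embeddings.labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 distinct labels")
    if counts.min() < 2:
        raise ValidationError("every label needs at least 2 members")
    x = embeddings.vectors
    if np.allclose(x, x[0], atol=1e-12):
        return 0.0
    return float(_sk_silhouette(x, labels, metric="euclidean"))


def best_atom_assignment(embeddings: EmbeddingSet) -> tuple[dict[int, str], float]:
    """Optimal atom-to-task map for argmax-attention task identification.

    The accuracy of a map ``g`` is ``mean(g(argmax alpha_i) == label_i)``;
    because each atom's contribution is independent, the exhaustive optimum
    assigns every atom its majority label among samples that select it.
    """
    arg = embeddings.vectors.argmax(axis=1)
    labels = np.asarray(embeddings.labels)
    assignment: dict[int, str] = {}
    correct = 0
    for atom in range(embeddings.vectors.shape[1]):
        sel = labels[arg == atom]
        if sel.size == 0:
            continue
        uniq, counts = np.unique(sel, return_counts=True)
        best = uniq[counts.argmax()]
        assignment[atom] = str(best)
        correct += int(counts.max())
    return assignment, correct / len(labels)


def separation_report(init_model: MiraNet, trained_model: MiraNet,
                      samples: Sequence[PairedSample]) -> SeparationReport:
    """Silhouette before vs after training, plus argmax-atom task accuracy."""
    before = silhouette_score(extract_embeddings(init_model, samples))
    emb_after = extract_embeddings(trained_model, samples)
    after = silhouette_score(emb_after)
    assignment, accuracy = best_atom_assignment(emb_after)
    return SeparationReport(silhouette_before=before, silhouette_after=after,
                            argmax_accuracy=accuracy, atom_assignment=assignment)


def embeddings_to_rows(embeddings: EmbeddingSet) -> list[dict]:
    """Flatten an embedding set for CSV export."""
    return [{"label": lab, **{f"alpha_{i}": float(v)
                              for i, v in enumerate(vec)}}
            for vec, lab in zip(embeddings.vectors, embeddings.labels)]


def __getattr__(name):
    # the unified-vs-single-task orchestration lives in miranet.experiment;
    # re-export lazily to avoid a circular import
    if name in ("ExperimentConfig", "ExperimentReport", "run_comparison_experiment"):
        from . import experiment

        return getattr(experiment, name)
    raise AttributeError(name)
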