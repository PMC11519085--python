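"""Template selection and pair construction.

A small set of representative labelled cases (templates) is chosen from the
training partition; every sample is then paired with every template and
represented by the signed feature-space difference ``V = M − N`` (template
minus sample). A pair is *positive* when template and sample share the
outcome class and *negative* otherwise — the binary target of the pair
classifier.

Per-class template counts follow the class frequencies (largest-remainder
apportionment with at least one template per class). The default ``medoid``
strategy picks, within each class, the samples minimizing the summed
Euclidean distance to all same-class samples — a deterministic stand-in for
the expert choice of representative cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import FeatureTable, PairlrError

logger = logging.getLogger("pairlr")


@dataclass
class TemplateSet:
    """Representative cases: ids, labels and processed-space feature vectors."""

    sample_ids: list[str]
    labels: np.ndarray
    vectors: np.ndarray
    strategy: str = "medoid"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not (len(self.sample_ids) == len(self.labels) == len(self.vectors)):
            raise PairlrError("template ids/labels/vectors length mismatch")

    @property
    def n_templates(self) -> int:
        return len(self.sample_ids)


@dataclass
class PairSet:
    """Template-sample difference vectors with pair labels and provenance."""

    vectors: np.ndarray               # (n_pairs, d)
    pair_labels: Optional[np.ndarray]  # 1 = positive pair, None if unknown
    template_ids: list[str]
    sample_ids: list[str]

    @property
    def n_pairs(self) -> int:
        return self.vectors.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "template_id": self.template_ids,
            "sample_id": self.sample_ids,
        })
        if self.pair_labels is not None:
            df["pair_label"] = self.pair_labels
        for j in range(self.vectors.shape[1]):
            df[f"v{j}"] = self.vectors[:, j]
        return df


def apportion_templates(class_counts: dict[int, int], n_templates: int) -> dict[int, int]:
    """Largest-remainder apportionment of template slots to classes, >= 1 each.

    E.g. 7 slots over class counts 45/46 give 3 event and 4 non-event
    templates (quotas 3.46 / 3.54).
    """
    if n_templates < 2:
        raise PairlrError("n_templates must be >= 2")
    classes = sorted(class_counts)
    if len(classes) < 2:
        raise PairlrError("both classes must be present to place templates")
    total = sum(class_counts.values())
    quotas = {c: n_templates * class_counts[c] / total for c in classes}
    alloc = {c: int(np.floor(quotas[c])) for c in classes}
    remaining = n_templates - sum(alloc.values())
    by_remainder = sorted(classes, key=lambda c: (-(quotas[c] - alloc[c]), c))
    for c in by_remainder[:remaining]:
        alloc[c] += 1
    # guarantee representation of every class
    for c in classes:
        if alloc[c] == 0:
            donor = max(classes, key=lambda k: (alloc[k], -k))
            alloc[donor] -= 1
            alloc[c] = 1
    for c in classes:
        if alloc[c] > class_counts[c]:
            raise PairlrError(
                f"class {c} has {class_counts[c]} samples but needs {alloc[c]} templates"
            )
    return alloc


def select_templates(
    table: FeatureTable,
    labels: np.ndarray,
    n_templates: int = 7,
    strategy: str = "medoid",
    manual_ids: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> TemplateSet:
    """Choose representative cases from the training table.

    ``medoid`` picks per-class distance-sum minimizers with ties broken by
    sample id; ``random`` draws per-class without replacement under the seed;
    ``manual`` takes ``manual_ids`` verbatim. Selection is invariant to the
    row order of the table (rows are canonicalized by sorted id first).
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != table.n_samples:
        raise PairlrError("labels length mismatch")
    if strategy == "manual":
        if not manual_ids:
            raise PairlrError("manual strategy requires manual_ids")
        index = {s: i for i, s in enumerate(table.sample_ids)}
        missing = [s for s in manual_ids if s not in index]
        if missing:
            raise PairlrError(f"manual template id(s) not in table: {missing}")
        idx = [index[s] for s in manual_ids]
        chosen = TemplateSet(
            sample_ids=[str(s) for s in manual_ids],
            labels=labels[idx],
            vectors=table.values[idx],
            strategy="manual",
        )
        if len(np.unique(chosen.labels)) < 2:
            logger.warning("manual templates cover a single class")
        return chosen
    if n_templates > table.n_samples:
        raise PairlrError("n_templates exceeds number of samples")
    counts = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    alloc = apportion_templates(counts, n_templates)
    # canonical row order: sorted by sample id
    order = sorted(range(table.n_samples), key=lambda i: table.sample_ids[i])
    rng = np.random.default_rng(seed)
    chosen_idx: list[int] = []
    for c in sorted(alloc):
        members = [i for i in order if labels[i] == c]
        k = alloc[c]
        if strategy == "medoid":
            xc = table.values[members]
            dist = np.sqrt(((xc[:, None, :] - xc[None, :, :]) ** 2).sum(axis=2))
            sums = dist.sum(axis=1)
            ranked = sorted(range(len(members)),
                            key=lambda m: (sums[m], table.sample_ids[members[m]]))
            chosen_idx.extend(members[m] for m in ranked[:k])
        elif strategy == "random":
            pick = rng.choice(len(members), size=k, replace=False)
            chosen_idx.extend(members[m] for m in sorted(pick))
        else:
            raise PairlrError(f"unknown template strategy {strategy!r}")
    chosen_idx.sort(key=lambda i: table.sample_ids[i])
    return TemplateSet(
        sample_ids=[table.sample_ids[i] for i in chosen_idx],
        labels=labels[chosen_idx],
        vectors=table.values[chosen_idx],
        strategy=strategy,
    )


def build_pairs(
    templates: TemplateSet,
    table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    exclude_self: bool = True,
    absolute: bool = False,
) -> PairSet:
    """Pair every sample with every template: ``V = M − N`` (signed).

    Pair labels are set by class agreement when sample labels are known.
    Self-pairs (a template matched with its own row, a zero vector) are
    excluded by default. ``absolute`` takes ``|M − N|`` for the distance
    reading of the pair vector.
    """
    if templates.vectors.shape[1] != table.n_features:
        raise PairlrError(
            f"dimension mismatch: templates have {templates.vectors.shape[1]} "
            f"features, table has {table.n_features}"
        )
    if labels is None:
        labels = table.labels
    if labels is not None:
        labels = np.asarray(labels, dtype=int)
        if len(labels) != table.n_samples:
            raise PairlrError("labels length mismatch")
    vecs, plabels, tids, sids = [], [], [], []
    for ti in range(templates.n_templates):
        for si in range(table.n_samples):
            if exclude_self and templates.sample_ids[ti] == table.sample_ids[si]:
                continue
            v = templates.vectors[ti] - table.values[si]
            vecs.append(np.abs(v) if absolute else v)
            tids.append(templates.sample_ids[ti])
            sids.append(table.sample_ids[si])
            if labels is not None:
                plabels.append(int(templates.labels[ti] == labels[si]))
    return PairSet(
        vectors=np.asarray(vecs, dtype=float).reshape(len(vecs), table.n_features),
        pair_labels=None if labels is None else np.asarray(plabels, dtype=int),
        template_ids=tids,
        sample_ids=sids,
    )
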