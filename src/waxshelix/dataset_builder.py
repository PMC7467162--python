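"""Labeled feature matrices for supervised learning on SWAXS profiles.

A :class:`LabeledDataset` row is one condition-modulated profile: the
features are log10 intensities on a common q grid, the labels are the five
structural descriptors of the generating conformation (computed once per
conformation from its bead structure and replicated across its
conditions), and a group key ties all of a conformation's rows together.

Splitting is conformation-grouped: every profile of one conformation lands
in the same train/validation/test partition, because the nine condition
profiles of a duplex are near-replicates that would otherwise leak
information across the split.  Test rows are hashed at split time and the
hash is re-checked before any final evaluation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import truncnorm

from . import descriptors as desc
from .helix_forge import DuplexModel
from .scattering import (
    DEFAULT_CONDITIONS,
    QGrid,
    SolutionCondition,
    apply_condition,
    debye_profile,
    make_qgrid,
)

SPLIT_TAGS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.68, 0.17, 0.15)


class DatasetError(ValueError):
    pass


@dataclass
class LabeledDataset:
    """Feature matrix + labels + grouping + split tags on one q grid."""

    features: np.ndarray          # (n_rows, n_q) log10 intensities
    labels: pd.DataFrame          # n_rows x the five descriptors
    groups: np.ndarray            # (n_rows,) conformation ids
    conditions: np.ndarray        # (n_rows,) condition names
    split: np.ndarray             # (n_rows,) '' or train/validation/test
    qgrid: QGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.features)
        if not (len(self.labels) == len(self.groups) == len(self.conditions)
                == len(self.split) == n):
            raise DatasetError("row counts of dataset components disagree")
        if self.features.shape[1] != len(self.qgrid):
            raise DatasetError("feature width does not match q grid")

    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def conformation_ids(self) -> np.ndarray:
        """Unique conformation ids in first-appearance order."""
        _, idx = np.unique(self.groups, return_index=True)
        return self.groups[np.sort(idx)]

    def rows(self, tag: str) -> np.ndarray:
        if tag not in SPLIT_TAGS:
            raise DatasetError(f"unknown split tag {tag!r}")
        return np.flatnonzero(self.split == tag)

    def copy(self) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features.copy(),
            labels=self.labels.copy(),
            groups=self.groups.copy(),
            conditions=self.conditions.copy(),
            split=self.split.copy(),
            qgrid=self.qgrid,
            meta=dict(self.meta),
        )

    def subset_conformations(self, keep: Sequence[str]) -> "LabeledDataset":
        mask = np.isin(self.groups, list(keep))
        return LabeledDataset(
            features=self.features[mask],
            labels=self.labels.iloc[mask].reset_index(drop=True),
            groups=self.groups[mask],
            conditions=self.conditions[mask],
            split=self.split[mask],
            qgrid=self.qgrid,
            meta=dict(self.meta),
        )


def assemble(
    models: Sequence[DuplexModel],
    conditions: Sequence[SolutionCondition] = DEFAULT_CONDITIONS,
    qgrid: QGrid | None = None,
    bead_width: float | None = None,
) -> LabeledDataset:
    """Profiles x conditions -> rows; descriptors computed once per model."""
    from .scattering import DEFAULT_BEAD_WIDTH

    qgrid = qgrid or make_qgrid()
    bead_width = DEFAULT_BEAD_WIDTH if bead_width is None else bead_width
    feats, rows, groups, conds = [], [], [], []
    dmax = 0.0
    for m in models:
        labels = desc.describe(m).as_dict()
        base = debye_profile(m, qgrid, bead_width=bead_width)
        dmax = max(dmax, m.max_distance())
        for c in conditions:
            prof = apply_condition(base, c)
            if np.any(prof.intensity <= 0):
                raise DatasetError(
                    f"non-positive intensity for conformation "
                    f"{m.conformation_id} under condition {c.name}"
                )
            feats.append(np.log10(prof.intensity))
            rows.append(labels)
            groups.append(m.conformation_id)
            conds.append(c.name)
    return LabeledDataset(
        features=np.array(feats),
        labels=pd.DataFrame(rows),
        groups=np.array(groups, dtype=object),
        conditions=np.array(conds, dtype=object),
        split=np.full(len(feats), "", dtype=object),
        qgrid=qgrid,
        meta={
            "dmax": dmax,
            "n_conditions": len(conditions),
            "condition_names": [c.name for c in conditions],
            "noise_level": 0.0,
        },
    )


def split_by_conformation(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> LabeledDataset:
    """Shuffle conformations and tag rows train/validation/test.

    Split sizes use floor rounding with the remainder assigned to training,
    so validation and test are never inflated past their nominal fractions;
    the test partition is fixed here, hashed, and must stay untouched until
    final evaluation (see :func:`verify_test_integrity`).
    """
    if len(fractions) != len(SPLIT_TAGS):
        raise DatasetError("three split fractions are required")
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise DatasetError("fractions must be positive and sum to 1")
    ids = dataset.conformation_ids
    if len(ids) < len(SPLIT_TAGS):
        raise DatasetError(
            f"{len(ids)} conformations cannot fill {len(SPLIT_TAGS)} splits"
        )
    rng = np.random.default_rng(seed)
    shuffled = ids[rng.permutation(len(ids))]
    n_val = int(len(ids) * fractions[1])
    n_test = int(len(ids) * fractions[2])
    n_train = len(ids) - n_val - n_test
    assignment: dict[str, str] = {}
    for cid in shuffled[:n_train]:
        assignment[cid] = "train"
    for cid in shuffled[n_train:n_train + n_val]:
        assignment[cid] = "validation"
    for cid in shuffled[n_train + n_val:]:
        assignment[cid] = "test"
    out = dataset.copy()
    out.split = np.array([assignment[g] for g in out.groups], dtype=object)
    out.meta["split_seed"] = seed
    out.meta["test_hash"] = _test_hash(out)
    return out


def _test_hash(dataset: LabeledDataset) -> str:
    idx = dataset.rows("test")
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.features[idx]).tobytes())
    h.update(dataset.labels.iloc[idx].to_numpy(dtype=float).tobytes())
    h.update(",".join(dataset.groups[idx]).encode())
    return h.hexdigest()


def verify_test_integrity(dataset: LabeledDataset) -> None:
    """Assert the held-out rows are byte-identical to those fixed at split."""
    expected = dataset.meta.get("test_hash")
    if expected is None:
        raise DatasetError("dataset has no recorded test hash; split it first")
    if _test_hash(dataset) != expected:
        raise DatasetError(
            "test rows changed since the split was made: refusing to evaluate"
        )


def implied_snr(relative_level: float) -> float:
    """Signal-to-noise ratio implied by a relative noise level (5% -> 20)."""
    if not 0 < relative_level < 1:
        raise DatasetError("relative noise level must be in (0, 1)")
    return 1.0 / relative_level


def add_noise(
    dataset: LabeledDataset,
    relative_level: float,
    seed: int = 0,
    tags: Sequence[str] | None = None,
) -> LabeledDataset:
    """Multiplicative Gaussian intensity noise, injected before the log.

    Each intensity is redrawn from Normal(I, level * I) truncated to
    positive values (the log feature is undefined otherwise); at the levels
    of interest (<= 0.30) truncation is a > 3-sigma event and the injected
    noise keeps an empirical sd of ~ level * I.

    ``tags`` restricts the injection to rows of those split tags (e.g.
    training rows only, as in the noisy-training experiments); the default
    noises every row.
    """
    if not 0 <= relative_level < 1:
        raise DatasetError("relative noise level must be in [0, 1)")
    out = dataset.copy()
    if relative_level == 0:
        return out
    if tags is None:
        idx = np.arange(out.n_rows)
    else:
        idx = np.concatenate([out.rows(t) for t in tags])
    intensities = 10.0 ** out.features[idx]
    rng = np.random.default_rng(seed)
    # standardized truncation bound is the same (-1/level) at every point
    draws = truncnorm.rvs(
        -1.0 / relative_level, np.inf, size=intensities.shape, random_state=rng
    )
    out.features[idx] = np.log10(intensities * (1.0 + relative_level * draws))
    out.meta["noise_level"] = relative_level
    if "test_hash" in out.meta:
        out.meta["test_hash"] = _test_hash(out)
    return out


def resample_qgrid(dataset: LabeledDataset, n_points: int) -> LabeledDataset:
    """Interpolate intensities onto ``n_points`` uniform q values.

    Piecewise-cubic interpolation of the smooth theoretical intensity
    curves over the original q range; extrapolation is impossible by
    construction and a request for it is rejected.
    """
    if n_points < 2:
        raise DatasetError("need at least 2 resampled q points")
    q = dataset.qgrid.values
    new_q = np.linspace(q[0], q[-1], n_points)
    out = dataset.copy()
    if len(new_q) == len(q) and np.allclose(new_q, q):
        out.meta["n_points"] = n_points
        return out
    intensities = 10.0 ** dataset.features
    interp = CubicSpline(q, intensities, axis=1)(new_q)
    if np.any(interp <= 0):
        raise DatasetError("resampled intensities are not strictly positive")
    out.features = np.log10(interp)
    out.qgrid = QGrid(new_q)
    out.meta["n_points"] = n_points
    if "test_hash" in out.meta:
        out.meta["test_hash"] = _test_hash(out)
    return out


def randomize_labels(dataset: LabeledDataset, seed: int = 0) -> LabeledDataset:
    """Control dataset: labels redrawn uniformly over their observed domain.

    Continuous descriptors are drawn uniformly over each column's observed
    [min, max]; the A-form class uniformly over the observed classes.
    Features are untouched, so any residual skill of a model trained here
    measures label-free structure, not scattering information.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    for col in desc.REGRESSION_DESCRIPTORS:
        lo, hi = out.labels[col].min(), out.labels[col].max()
        out.labels[col] = rng.uniform(lo, hi, out.n_rows)
    classes = np.unique(out.labels[desc.CLASSIFIER_DESCRIPTOR])
    out.labels[desc.CLASSIFIER_DESCRIPTOR] = rng.choice(classes, out.n_rows)
    out.meta["randomized_labels"] = True
    if "test_hash" in out.meta:
        out.meta["test_hash"] = _test_hash(out)
    return out


# ---------------------------------------------------------------------------
# persistence

def save_h5(dataset: LabeledDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=dataset.features)
        f.create_dataset("q", data=dataset.qgrid.values)
        for col in dataset.labels.columns:
            f.create_dataset(f"labels/{col}", data=dataset.labels[col].to_numpy())
        str_dt = h5py.string_dtype()
        for name, arr in (("groups", dataset.groups),
                          ("conditions", dataset.conditions),
                          ("split", dataset.split)):
            f.create_dataset(name, data=[str(x).encode() for x in arr], dtype=str_dt)
        for k, v in dataset.meta.items():
            if isinstance(v, (list, tuple)):
                f.attrs[k] = [str(x) for x in v]
            else:
                f.attrs[k] = v


def load_h5(path: str | Path) -> LabeledDataset:
    with h5py.File(path, "r") as f:
        labels = pd.DataFrame(
            {col: f[f"labels/{col}"][:] for col in f["labels"].keys()}
        )[list(desc.DESCRIPTOR_NAMES)]
        meta = {}
        for k, v in f.attrs.items():
            meta[k] = list(v) if isinstance(v, np.ndarray) else v
        return LabeledDataset(
            features=f["features"][:],
            labels=labels,
            groups=f["groups"].asstr()[:].astype(object),
            conditions=f["conditions"].asstr()[:].astype(object),
            split=f["split"].asstr()[:].astype(object),
            qgrid=QGrid(f["q"][:]),
            meta=meta,
        )


def export_csv(dataset: LabeledDataset, path: str | Path) -> None:
    """Flat CSV for inspection: metadata columns, labels, then features."""
    df = pd.DataFrame(
        {
            "conformation_id": dataset.groups,
            "condition": dataset.conditions,
            "split": dataset.split,
        }
    )
    df = pd.concat([df, dataset.labels.reset_index(drop=True)], axis=1)
    feat = pd.DataFrame(
        dataset.features,
        columns=[f"logI_q{q:.4f}" for q in dataset.qgrid.values],
    )
    pd.concat([df, feat], axis=1).to_csv(path, index=False)
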