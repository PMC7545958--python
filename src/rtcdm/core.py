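"""Core domain types: Q-matrix, latent classes, datasets, and text I/O.

A cognitive diagnostic model (CDM) links J test items to K binary skills
("attributes") through a J×K binary Q-matrix: ``q[j, k] == 1`` means a
correct answer to item j requires attribute k.  A person's latent state is
an attribute profile α ∈ {0,1}^K plus a working-speed parameter τ (an
offset on the log response-time scale).  The 2^K possible profiles are the
latent classes of the model.

Q-matrix identifiability is *not* checked here — no general algorithmic
criterion is implemented; users should verify identifiability with the
dedicated literature/tools before trusting attribute estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "validate_qmatrix",
    "enumerate_latent_classes",
    "reduced_profile",
    "mastery_matrix",
    "PersonState",
    "BehaviorIndicator",
    "Dataset",
    "read_qmatrix",
    "write_qmatrix",
    "read_matrix_csv",
    "write_matrix_csv",
]

ModelForm = Literal["DINA", "DINO", "GDINA"]

MAX_ATTRIBUTES = 15  # 2^K classes are enumerated explicitly


@dataclass(frozen=True)
class QMatrix:
    """Validated J×K binary skill-requirement matrix.

    Attributes
    ----------
    q : ndarray of int8, shape (J, K)
        Binary entries; ``q[j, k] == 1`` iff item j requires attribute k.
    required_count : ndarray of int, shape (J,)
        K*_j = number of attributes required by each item (row sums, all ≥ 1).
    """

    q: np.ndarray
    required_count: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q)
        if q.ndim != 2 or q.size == 0:
            raise ValueError("Q-matrix must be a non-empty 2-D table")
        if not np.isin(q, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        q = q.astype(np.int8)
        ksr = q.sum(axis=1)
        if (ksr == 0).any():
            bad = int(np.flatnonzero(ksr == 0)[0])
            raise ValueError(f"item {bad} requires no attribute (all-zero row)")
        if (q.sum(axis=0) == 0).any():
            bad = int(np.flatnonzero(q.sum(axis=0) == 0)[0])
            raise ValueError(f"attribute {bad} is required by no item (all-zero column)")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "required_count", ksr.astype(int))

    @property
    def n_items(self) -> int:
        return self.q.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.q.shape[1]


def validate_qmatrix(raw_table) -> QMatrix:
    """Validate a raw integer table and return a :class:`QMatrix`.

    Raises ``ValueError`` for non-binary entries, an all-zero row (an item
    requiring nothing) or an all-zero column (an attribute never measured).
    """
    arr = np.asarray(raw_table)
    if arr.ndim != 2:
        raise ValueError("Q-matrix must be rectangular (2-D)")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("Q-matrix entries must be numeric 0/1")
    return QMatrix(arr)


def enumerate_latent_classes(n_attributes: int) -> np.ndarray:
    """All 2^K attribute profiles in binary-counting order.

    Attribute 1 is the least-significant bit: class c has
    ``profile[k] = (c >> k) & 1``.  This ordering is stable and is the
    class index used throughout posterior summaries.

    Returns an int8 array of shape (2^K, K).
    """
    if not 1 <= n_attributes <= MAX_ATTRIBUTES:
        raise ValueError(f"n_attributes must be in [1, {MAX_ATTRIBUTES}]")
    c = np.arange(2 ** n_attributes)[:, None]
    k = np.arange(n_attributes)[None, :]
    return ((c >> k) & 1).astype(np.int8)


def reduced_profile(alpha: np.ndarray, qrow: np.ndarray) -> np.ndarray:
    """Subvector α*_j of a profile at the attributes item j requires."""
    alpha = np.asarray(alpha)
    qrow = np.asarray(qrow)
    return alpha[qrow == 1]


def mastery_matrix(qmatrix: QMatrix, profiles: np.ndarray, model_form: str) -> np.ndarray:
    """Deterministic "gate" indicator for every (class, item) pair.

    DINA (non-compensatory): 1 iff the profile masters *all* required
    attributes.  DINO (compensatory): 1 iff it masters *at least one*.
    Shape (2^K, J), boolean.
    """
    hits = profiles @ qmatrix.q.T  # (C, J) count of mastered required attrs
    if model_form == "DINA":
        return hits == qmatrix.required_count[None, :]
    if model_form == "DINO":
        return hits > 0
    raise ValueError(f"mastery gate undefined for model_form={model_form!r}")


@dataclass(frozen=True)
class PersonState:
    """Latent state of one test-taker: attribute profile and speed τ."""

    profile: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        p = np.asarray(self.profile, dtype=np.int8)
        if not np.isin(p, (0, 1)).all():
            raise ValueError("attribute profile entries must be 0/1")
        if not np.isfinite(self.tau):
            raise ValueError("speed τ must be finite")
        object.__setattr__(self, "profile", p)


@dataclass(frozen=True)
class BehaviorIndicator:
    """I×J binary matrix ξ: 1 = solution attempt, 0 = rapid guess."""

    xi: np.ndarray

    def __post_init__(self) -> None:
        xi = np.asarray(self.xi)
        if not np.isin(xi, (0, 1)).all():
            raise ValueError("ξ entries must be 0/1")
        object.__setattr__(self, "xi", xi.astype(np.int8))


@dataclass
class Dataset:
    """Complete response/response-time data for one test administration.

    Y and RT are I×J with no missing cells (records with missing responses
    must be screened out before analysis; no imputation is offered).  The
    optional ``truth`` dict is populated by the simulator and holds the
    generating latents and parameters.
    """

    Y: np.ndarray
    RT: np.ndarray
    qmatrix: QMatrix
    truth: Optional[dict] = None
    item_labels: Optional[list] = None

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y)
        RT = np.asarray(self.RT, dtype=float)
        if Y.ndim != 2 or Y.shape != RT.shape:
            raise ValueError(
                f"responses {Y.shape} and response times {RT.shape} must share an I×J shape"
            )
        if Y.shape[1] != self.qmatrix.n_items:
            raise ValueError(
                f"data have {Y.shape[1]} items but the Q-matrix has {self.qmatrix.n_items}"
            )
        if np.isnan(Y.astype(float)).any() or np.isnan(RT).any():
            raise ValueError("missing cells are not supported; screen incomplete records out")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")
        if not (RT > 0).all():
            raise ValueError("all response times must be positive (seconds)")
        self.Y = Y.astype(np.int8)
        self.RT = RT
        if self.item_labels is None:
            self.item_labels = [f"item{j + 1}" for j in range(Y.shape[1])]

    @property
    def n_persons(self) -> int:
        return self.Y.shape[0]

    @property
    def n_items(self) -> int:
        return self.Y.shape[1]


# ---------------------------------------------------------------------------
# Text I/O.  Q-matrix: headerless delimited 0/1.  Y/RT: one header row of
# item labels, one row per person, full precision.
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    first = Path(path).read_text().splitlines()[0]
    return "\t" if "\t" in first else ","


def read_qmatrix(path) -> QMatrix:
    """Read a headerless comma- or tab-delimited J×K 0/1 table."""
    path = Path(path)
    df = pd.read_csv(path, header=None, sep=_sniff_sep(path))
    return validate_qmatrix(df.to_numpy())


def write_qmatrix(qmatrix: QMatrix, path) -> None:
    pd.DataFrame(qmatrix.q).to_csv(path, header=False, index=False)


def read_matrix_csv(path) -> tuple[np.ndarray, list]:
    """Read an I×J matrix with one header row of item labels."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return df.to_numpy(), list(df.columns)


def write_matrix_csv(mat: np.ndarray, labels, path) -> None:
    pd.DataFrame(np.asarray(mat), columns=list(labels)).to_csv(
        path, index=False, float_format="%.17g"
    )
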