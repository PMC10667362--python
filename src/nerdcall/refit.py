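"""Signature refitting by non-negative least squares.

Given a fixed matrix of indel signatures S (83 channels x K signatures,
columns summing to one) and a per-sample catalog c, the exposure vector
e solves

    minimize ||c - S e||_2   subject to  e >= 0,

a convex problem solved to its global optimum.  Exposures are reported
in attributed-mutation-count units and are not renormalized; the ID8
component of e is the quantity later thresholded to call NER deficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .channels import ID83_LABELS, LABEL_INDEX, ChannelId
from .errors import ConfigurationError, FormatError

COLUMN_SUM_TOL = 1e-6


@dataclass
class ExposureVector:
    """Nonnegative signature activities for one sample.

    ``residual_norm`` is the Euclidean norm of catalog minus
    reconstruction at the optimum.
    """

    sample_id: str
    exposures: dict[str, float]
    residual_norm: float


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated signature definition matrix.

    First column: ID-83 channel labels (zero-based layout, e.g.
    ``1:Del:C:0``); remaining columns: signatures.  Rows are reordered to
    the canonical catalog order; missing or unknown channels, negative
    entries and columns not summing to one are format errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_signature_matrix(df, origin=str(path))


def validate_signature_matrix(df: pd.DataFrame, origin: str = "signature matrix") -> pd.DataFrame:
    labels = [str(lab).strip() for lab in df.index]
    for lab in labels:
        ChannelId.from_label(lab)  # raises FormatError on unknown labels
    seen = set(labels)
    missing = [lab for lab in ID83_LABELS if lab not in seen]
    if missing:
        raise FormatError(f"{origin}: missing channel row(s) {missing[:3]}" +
                          ("..." if len(missing) > 3 else ""))
    if len(seen) != len(labels):
        raise FormatError(f"{origin}: duplicated channel rows")
    df = df.copy()
    df.index = labels
    df = df.loc[list(ID83_LABELS)]
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{origin}: non-numeric entries")
    if (values < 0).any():
        raise FormatError(f"{origin}: negative signature entries")
    sums = values.sum(axis=0)
    bad = np.abs(sums - 1.0) > COLUMN_SUM_TOL
    if bad.any():
        name = df.columns[int(np.argmax(bad))]
        raise FormatError(
            f"{origin}: column {name!r} sums to {sums[np.argmax(bad)]:.6f}, expected 1"
        )
    return df


def toy_signature_matrix() -> pd.DataFrame:
    """A deterministic 3-signature (ID1, ID2, ID8) matrix for fast tests.

    ID1 loads on 1 bp T insertions in homopolymers, ID2 on 1 bp T
    deletions in homopolymers, and ID8 on long (>=4-5 bp) deletions with
    no or 1-2 bp flanking microhomology — the shape of the
    NER-deficiency signature.  Supports are disjoint, so the columns are
    linearly independent.
    """
    data = {
        "ID1": {
            "1:Ins:T:0": 0.05,
            "1:Ins:T:1": 0.10,
            "1:Ins:T:2": 0.15,
            "1:Ins:T:3": 0.20,
            "1:Ins:T:4": 0.25,
            "1:Ins:T:5": 0.25,
        },
        "ID2": {
            "1:Del:T:0": 0.05,
            "1:Del:T:1": 0.10,
            "1:Del:T:2": 0.15,
            "1:Del:T:3": 0.20,
            "1:Del:T:4": 0.25,
            "1:Del:T:5": 0.25,
        },
        "ID8": {
            "5:Del:R:0": 0.40,
            "5:Del:M:1": 0.30,
            "5:Del:M:2": 0.20,
            "4:Del:R:0": 0.05,
            "4:Del:M:1": 0.05,
        },
    }
    mat = pd.DataFrame(0.0, index=list(ID83_LABELS), columns=list(data))
    for sig, weights in data.items():
        for lab, w in weights.items():
            mat.loc[lab, sig] = w
    return validate_signature_matrix(mat, origin="toy signature matrix")


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """NNLS exposure estimator against a fixed signature matrix.

    Parameters
    ----------
    signatures:
        Signature matrix (DataFrame 83 x K in canonical or arbitrary row
        order) or a path to a tab-separated file.
    subset:
        Optional list of signature names to restrict the refit to.

    Attributes
    ----------
    signatures_ : DataFrame
        Validated matrix in canonical row order.
    signature_names_ : list of str
    """

    def __init__(self, signatures=None, subset=None):
        self.signatures = signatures
        self.subset = subset

    def fit(self, X=None, y=None):
        if self.signatures is None:
            raise ConfigurationError("SignatureRefitter requires a signature matrix")
        if isinstance(self.signatures, (str, Path)):
            sigs = read_signature_matrix(self.signatures)
        else:
            sigs = validate_signature_matrix(self.signatures)
        if self.subset is not None:
            unknown = [s for s in self.subset if s not in sigs.columns]
            if unknown:
                raise ConfigurationError(f"unknown signature(s) in subset: {unknown}")
            sigs = sigs[list(self.subset)]
        self.signatures_ = sigs
        self.signature_names_ = list(sigs.columns)
        values = sigs.to_numpy(dtype=float)
        if np.linalg.matrix_rank(values) < values.shape[1]:
            warnings.warn(
                "signature columns are collinear; NNLS exposures may be "
                "non-unique (the solver's optimum is reported)",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def _check_fitted(self):
        if not hasattr(self, "signatures_"):
            raise ConfigurationError("SignatureRefitter is not fitted")

    def transform(self, X) -> pd.DataFrame:
        """Exposures for each catalog row (samples x K DataFrame)."""
        exp, _ = self._solve(X)
        return exp

    def refit(self, X) -> pd.DataFrame:
        """Exposures plus a ``residual_norm`` column."""
        exp, res = self._solve(X)
        exp = exp.copy()
        exp["residual_norm"] = res
        return exp

    def _solve(self, X):
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            missing = [c for c in ID83_LABELS if c not in X.columns]
            if missing:
                raise ConfigurationError(
                    f"catalog is missing channel column(s), e.g. {missing[0]!r}"
                )
            index = X.index
            counts = X[list(ID83_LABELS)].to_numpy(dtype=float)
        else:
            counts = np.atleast_2d(np.asarray(X, dtype=float))
            index = pd.RangeIndex(counts.shape[0])
        if counts.shape[1] != 83:
            raise ConfigurationError(
                f"catalog must have 83 channels, got {counts.shape[1]}"
            )
        S = self.signatures_.to_numpy(dtype=float)
        expo = np.empty((counts.shape[0], S.shape[1]))
        resid = np.empty(counts.shape[0])
        for i in range(counts.shape[0]):
            expo[i], resid[i] = nnls(S, counts[i])
        return (
            pd.DataFrame(expo, index=index, columns=self.signature_names_),
            resid,
        )


def nnls_refit(catalog, sigs, sample_id: str = "") -> ExposureVector:
    """Refit a single 83-channel catalog against a signature matrix.

    ``catalog`` may be an 83-vector (canonical order) or a pandas Series
    indexed by channel label.
    """
    refitter = SignatureRefitter(signatures=sigs).fit()
    if isinstance(catalog, pd.Series):
        row = catalog.reindex(list(ID83_LABELS))
        if row.isna().any():
            raise ConfigurationError("catalog series is missing channel entries")
        counts = row.to_numpy(dtype=float)[None, :]
    else:
        counts = np.asarray(catalog, dtype=float)[None, :]
    exp = refitter.refit(counts)
    exposures = {s: float(exp.iloc[0][s]) for s in refitter.signature_names_}
    return ExposureVector(sample_id, exposures, float(exp.iloc[0]["residual_norm"]))


def id8_exposure(e: ExposureVector) -> float:
    """The absolute ID8 exposure (unrounded attributed deletion count)."""
    if "ID8" not in e.exposures:
        raise ConfigurationError("signature matrix does not contain ID8")
    return float(e.exposures["ID8"])
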