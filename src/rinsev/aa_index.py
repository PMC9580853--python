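"""The 20x20 amino-acid distance index.

A large numeric amino-acid property matrix (AAindex-style, one row per
physicochemical property, one column per amino acid) is standardized,
reduced by PCA to the smallest number of components retaining a target
fraction of the variance (default 99%), and pairwise Euclidean distances
between the 20 amino-acid score vectors form the distance index.

The canonical 544-property collection can be obtained at run time from
the R package seqinr (``data(aaindex)``) via :func:`fetch_aaindex`;
properties with any missing amino-acid entry are dropped (no
imputation).
"""

from __future__ import annotations

import io
import logging
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .chem import AA_3TO1, AA_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "PropertyMatrix",
    "AADistanceIndex",
    "load_property_matrix",
    "fetch_aaindex",
    "pca_reduce",
    "distance_matrix",
    "build_distance_index",
]


@dataclass
class PropertyMatrix:
    """Properties x 20 amino acids; ``data`` may contain missing values."""

    data: pd.DataFrame  # index: property id, columns: AA_ORDER

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(AA_ORDER):
            raise ValueError("property matrix must have exactly the 20 standard "
                             "amino-acid columns in canonical order")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate property ids: {dups[:5]}")

    @property
    def n_properties(self) -> int:
        return len(self.data)

    def complete(self) -> pd.DataFrame:
        """Rows without missing values (dropped count logged)."""
        out = self.data.dropna()
        dropped = len(self.data) - len(out)
        if dropped:
            logger.info("dropped %d/%d properties with missing values",
                        dropped, len(self.data))
        return out


@dataclass
class AADistanceIndex:
    """Symmetric 20x20 Euclidean distance matrix in PCA component space."""

    matrix: pd.DataFrame
    n_components: int
    variance_retained: float
    standardized: bool = True

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.matrix.loc[a, b])


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Accept 1- or 3-letter amino-acid column names; reorder canonically."""
    rename = {}
    for c in df.columns:
        cu = str(c).strip()
        if cu.upper() in AA_3TO1:
            rename[c] = AA_3TO1[cu.upper()]
        elif len(cu) == 1 and cu.upper() in AA_ORDER:
            rename[c] = cu.upper()
    df = df.rename(columns=rename)
    missing = [a for a in AA_ORDER if a not in df.columns]
    if missing:
        raise ValueError(f"property table lacks amino-acid columns: {missing}")
    return df[list(AA_ORDER)]


def load_property_matrix(source) -> PropertyMatrix:
    """Load a property table (TSV path/buffer or DataFrame).

    The first column (or the index) holds property ids; amino-acid
    columns may use 1- or 3-letter codes in any order.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", index_col=0)
    if df.index.name is None and df.columns[0].lower() in ("property_id", "id"):
        df = df.set_index(df.columns[0])
    return PropertyMatrix(_normalize_columns(df).astype(float))


_R_SNIPPET = (
    "suppressMessages(library(seqinr)); data(aaindex);"
    "m <- sapply(aaindex, function(x) x$I);"
    "write.table(t(m), stdout(), sep='\\t', quote=FALSE)"
)


def fetch_aaindex(rscript: str = "Rscript") -> PropertyMatrix:
    """Obtain the 544-property aaindex collection from R's seqinr package.

    Runs a small R snippet through ``Rscript``; the data ships with
    seqinr, so no network access is needed.
    """
    try:
        proc = subprocess.run([rscript, "-e", _R_SNIPPET], capture_output=True,
                              text=True, check=True, timeout=120)
    except (OSError, subprocess.SubprocessError) as exc:
        raise RuntimeError(
            "could not obtain the aaindex property table via Rscript/seqinr; "
            "provide a property table file instead") from exc
    return load_property_matrix(io.StringIO(proc.stdout))


def pca_reduce(pm: PropertyMatrix, variance_target: float = 0.99,
               standardize: bool = True):
    """PCA scores of the 20 amino acids over the complete properties.

    Properties are standardized to zero mean / unit variance across the
    20 amino acids (zero-variance properties dropped, logged) unless
    ``standardize=False``.  Returns (scores DataFrame 20 x k, k,
    variance retained at k).
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    props = pm.complete()
    if len(props) < 2:
        raise ValueError("need at least 2 complete properties for PCA")
    X = props.to_numpy(dtype=float).T  # 20 amino acids x properties
    if standardize:
        sd = X.std(axis=0)
        degenerate = sd == 0
        if degenerate.any():
            logger.info("dropped %d zero-variance properties", int(degenerate.sum()))
            X = X[:, ~degenerate]
            sd = sd[~degenerate]
        X = (X - X.mean(axis=0)) / sd
    pca = PCA()
    scores_full = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, scores_full.shape[1])
    scores = pd.DataFrame(scores_full[:, :k], index=list(AA_ORDER),
                          columns=[f"PC{i+1}" for i in range(k)])
    return scores, k, float(cum[k - 1])


def distance_matrix(scores: pd.DataFrame) -> AADistanceIndex:
    """Pairwise Euclidean distances between amino-acid component vectors."""
    if set(scores.index) != set(AA_ORDER):
        raise ValueError("scores must cover exactly the 20 standard amino acids")
    scores = scores.loc[list(AA_ORDER)]
    dm = squareform(pdist(scores.to_numpy(dtype=float)))
    return AADistanceIndex(
        matrix=pd.DataFrame(dm, index=list(AA_ORDER), columns=list(AA_ORDER)),
        n_components=scores.shape[1],
        variance_retained=np.nan,
    )


def build_distance_index(pm: PropertyMatrix | None = None,
                         variance_target: float = 0.99,
                         standardize: bool = True) -> AADistanceIndex:
    """Property matrix -> PCA -> distance index (fetches aaindex if None)."""
    if pm is None:
        pm = fetch_aaindex()
    scores, k, retained = pca_reduce(pm, variance_target=variance_target,
                                     standardize=standardize)
    idx = distance_matrix(scores)
    idx.n_components = k
    idx.variance_retained = retained
    idx.standardized = standardize
    return idx
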