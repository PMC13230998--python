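"""Empirical UMI-multiplicity spectra: per-cell N_k and depth-binned means.

``N_ik`` is the number of genes observed exactly ``k`` times in cell ``i``;
summing ``k * N_ik`` over k recovers the cell's total UMI count.  Cells are
stratified into depth bins of width 1,000 and ``N̄_k``, the per-bin mean of
``N_ik``, is the profile compared against model-expected spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["NkProfile", "per_cell_nk", "bin_mean_nk"]


@dataclass
class NkProfile:
    """Depth-binned mean multiplicity spectrum.

    ``mean_nk`` is a DataFrame indexed by bin lower edge (half-open bins
    [b*w, (b+1)*w)) with columns k = 1..k_max; bins containing no cells are
    dropped entirely rather than stored as zeros.
    """

    bin_width: int
    mean_nk: pd.DataFrame
    cells_per_bin: pd.Series

    def to_tsv(self, path) -> None:
        out = self.mean_nk.copy()
        out.insert(0, "n_cells", self.cells_per_bin)
        out.index.name = "depth_bin_start"
        out.to_csv(path, sep="\t")


def per_cell_nk(counts, k_max: int | None = None) -> np.ndarray:
    """Count genes observed exactly k times per cell.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes x cells (dense or sparse).
    k_max
        Largest multiplicity column; defaults to the observed maximum.

    Returns
    -------
    (n_cells, k_max) integer array; column j holds N_{k=j+1} (k = 0 excluded).
    """
    if sp.issparse(counts):
        mat = counts.tocsc()
        data_all = mat.data
        if data_all.size and (np.any(data_all < 0) or np.any(data_all != np.floor(data_all))):
            raise ValueError("counts must be non-negative integers")
        observed_max = int(data_all.max()) if data_all.size else 0
        if k_max is None:
            k_max = max(observed_max, 1)
        n_cells = mat.shape[1]
        out = np.zeros((n_cells, k_max), dtype=np.int64)
        for j in range(n_cells):
            col = mat.data[mat.indptr[j] : mat.indptr[j + 1]].astype(np.int64)
            if col.size:
                bc = np.bincount(col, minlength=k_max + 1)
                out[j, :] = bc[1 : k_max + 1]
        return out
    arr = np.asarray(counts)
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer) and np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = arr.astype(np.int64)
    if k_max is None:
        k_max = max(int(arr.max(initial=0)), 1)
    n_cells = arr.shape[1]
    out = np.zeros((n_cells, k_max), dtype=np.int64)
    for j in range(n_cells):
        bc = np.bincount(arr[:, j], minlength=k_max + 1)
        out[j, :] = bc[1 : k_max + 1]
    return out


def bin_mean_nk(
    nk_matrix: np.ndarray, totals: np.ndarray, bin_width: int = 1_000
) -> NkProfile:
    """Average N_ik over cells stratified by total UMI into width-w bins.

    Bin b covers totals in [b*w, (b+1)*w); empty bins are absent from the
    result.  Each row of ``nk_matrix`` must satisfy sum_k k*N_ik = totals[i],
    which is checked before averaging.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nk_matrix = np.asarray(nk_matrix)
    totals = np.asarray(totals)
    if nk_matrix.shape[0] != totals.size:
        raise ValueError("totals length must match rows of nk_matrix")
    k = np.arange(1, nk_matrix.shape[1] + 1)
    recovered = nk_matrix @ k
    if not np.array_equal(recovered, totals):
        raise ValueError("sum_k k*N_ik does not reproduce the provided totals")
    bins = totals // bin_width
    df = pd.DataFrame(nk_matrix, columns=k)
    grouped = df.groupby(bins * bin_width)
    mean = grouped.mean()
    counts = grouped.size()
    mean.index.name = "depth_bin_start"
    return NkProfile(bin_width=int(bin_width), mean_nk=mean, cells_per_bin=counts)
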