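"""Readers, writers and fixture generation.

Tabular files are TSV by default (tab-separated, header row, '.' decimal,
UTF-8); CSV is accepted on read and detected from the file extension.
Count matrices may also be MatrixMarket ``.mtx`` with companion gene and
sample id files.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from nbdiag.nb_fit import DesignSpec
from nbdiag.multigene import CountMatrix


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_regression_table(
    path,
    response: str = "count",
    offset: Optional[str] = None,
    add_intercept: bool = True,
):
    """Read a single-response regression table.

    The ``response`` column holds the counts; an optional ``offset``
    column holds log-scale offsets; every other numeric column is a
    covariate.  Returns ``(y, DesignSpec)``.
    """
    df = _read_table(path)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found in {path}")
    y = df[response].to_numpy()
    off = df[offset].to_numpy(dtype=float) if offset and offset in df.columns else None
    covars = [c for c in df.columns if c not in (response, offset)]
    X = df[covars].to_numpy(dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
    return y, DesignSpec(X, off)


def write_regression_table(path, y, x, colnames=("count", "x")) -> None:
    pd.DataFrame({colnames[0]: y, colnames[1]: x}).to_csv(path, sep="\t", index=False)


def read_count_matrix(
    path,
    lib_sizes: Optional[np.ndarray] = None,
    norm_factors_path=None,
) -> CountMatrix:
    """Read a genes x samples count matrix.

    TSV/CSV with gene ids in the first column, or MatrixMarket ``.mtx``
    with sibling ``<stem>.genes.txt`` / ``<stem>.samples.txt`` id files.
    Optional normalization factors come from a two-column TSV
    (sample_id, factor).
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        from scipy.io import mmread

        counts = np.asarray(mmread(path).todense())
        genes = path.with_suffix("").with_suffix(".genes.txt")
        samples = path.with_suffix("").with_suffix(".samples.txt")
        gene_ids = genes.read_text().split() if genes.exists() else None
        sample_ids = samples.read_text().split() if samples.exists() else None
    else:
        df = _read_table(path)
        gene_ids = df.iloc[:, 0].astype(str).tolist()
        sample_ids = list(df.columns[1:])
        counts = df.iloc[:, 1:].to_numpy()
    nf = None
    if norm_factors_path is not None:
        nf_df = _read_table(norm_factors_path)
        nf = nf_df.iloc[:, 1].to_numpy(dtype=float)
    return CountMatrix(
        counts=counts,
        lib_sizes=lib_sizes,
        norm_factors=nf,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
    )


def write_count_matrix(path, cm: CountMatrix) -> None:
    df = pd.DataFrame(cm.counts, columns=cm.sample_ids)
    df.insert(0, "gene_id", cm.gene_ids)
    df.to_csv(path, sep="\t", index=False)


def read_design(path, add_intercept: bool = True) -> DesignSpec:
    """Read a samples x covariates design table (all columns numeric)."""
    df = _read_table(path)
    X = df.to_numpy(dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
    return DesignSpec(X)


def read_plugin_dispersions(path, gene_ids=None) -> np.ndarray:
    """Read per-gene plug-in dispersions from a two-column (gene_id, phi) TSV."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ValueError("plug-in dispersion file needs gene_id and phi columns")
    table = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
    if gene_ids is None:
        return np.array(list(table.values()))
    missing = [g for g in gene_ids if str(g) not in table]
    if missing:
        raise ValueError(f"{len(missing)} genes missing from dispersion file")
    return np.array([table[str(g)] for g in gene_ids])


def run_metadata(seed, config: dict) -> dict:
    """Reproducibility block recorded with every CLI run."""
    import nbdiag

    payload = json.dumps(config, sort_keys=True, default=str)
    return {
        "package_version": nbdiag.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
        "config_sha1": hashlib.sha1(payload.encode()).hexdigest(),
    }


def make_fixture_loglinear(
    out_dir,
    n: int = 45,
    beta: tuple = (20.7, -2.3),
    x_range: tuple = (4.5, 9.1),
    phi: float = 0.05,
    seed: Optional[int] = None,
):
    """Write a synthetic log-linear count fixture (magnitude-frequency style).

    Emulates the structure of an earthquake magnitude-frequency regression
    (counts falling roughly tenfold per unit of the covariate, following a
    Gutenberg-Richter-type law): a ``count`` column of NB2 draws against a
    covariate grid.  Purely synthetic; defaults give 45 rows over
    magnitudes 4.5 to 9.1.
    """
    if n < 3:
        raise ValueError("need at least 3 rows")
    from nbdiag.nb_models import simulate_nb_arrays

    rng = np.random.default_rng(seed)
    x = np.linspace(x_range[0], x_range[1], n)
    mu = np.exp(beta[0] + beta[1] * x)
    y = simulate_nb_arrays(mu, phi, rng)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "loglinear_counts.tsv"
    write_regression_table(path, y, np.round(x, 6), colnames=("count", "magnitude"))
    return path
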