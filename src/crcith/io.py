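"""Plain-text readers/writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse

from crcith.protein import NPXData


def read_counts(path: str | Path) -> pd.DataFrame:
    """Counts as genes x samples from TSV, or MatrixMarket with index files.

    For ``X.mtx``, row ids are read from ``X.rows.txt`` and column ids from
    ``X.cols.txt`` (one id per line).
    """
    path = Path(path)
    if path.suffix == ".mtx":
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        rows = (path.parent / (path.stem + ".rows.txt")).read_text().split()
        cols = (path.parent / (path.stem + ".cols.txt")).read_text().split()
        return pd.DataFrame(m, index=rows, columns=cols)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(counts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
    (path.parent / (path.stem + ".rows.txt")).write_text("\n".join(counts.index))
    (path.parent / (path.stem + ".cols.txt")).write_text("\n".join(counts.columns))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_npx(path: str | Path, detected_path: str | Path | None = None,
             flag_column: str = "qc_flagged") -> NPXData:
    """Olink-style wide CSV: rows = samples, columns = proteins.

    An optional ``qc_flagged`` boolean column marks failed samples; a
    companion detection CSV of the same shape carries detection flags
    (missing -> everything counts as detected).
    """
    values = pd.read_csv(path, index_col=0)
    flagged = pd.Series(False, index=values.index)
    if flag_column in values.columns:
        flagged = values.pop(flag_column).astype(bool)
    if detected_path is not None:
        detected = pd.read_csv(detected_path, index_col=0).astype(bool)
        detected = detected.reindex(index=values.index, columns=values.columns)
        detected = detected.fillna(False)
    else:
        detected = values.notna()
    return NPXData(values=values, detected=detected, flagged=flagged)


def read_panels(path: str | Path) -> dict[str, list[str]]:
    """Panel definition TSV: panel name, semicolon-separated member proteins."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = df.columns[0]
    return {name: str(row[col]).split(";") for name, row in df.iterrows()}
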