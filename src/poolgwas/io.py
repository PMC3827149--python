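"""Tab-separated I/O with provenance header comments.

Every table the pipeline writes starts with ``#``-prefixed comment lines
carrying the config hash and seed, so any stage can be re-run from its
persisted inputs and audited against the manifest.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a DataFrame as UTF-8 TSV with a mandatory header row, preceded by
    ``# key=value`` comment lines for each item of ``meta``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, ignoring comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_tsv_meta(path: str | Path) -> dict:
    """Recover the ``# key=value`` comment header of a TSV."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta
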