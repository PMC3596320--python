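"""TSV readers/writers and provenance headers for all pipeline tables.

All tables are tab-separated with a header row; missing values are encoded
as ``ND`` (matching the not-determined convention of half-life supplements).
Intensity matrices store genes as rows and membranes as columns whose names
encode the replicate structure, ``B<bio>T<tech>_t<minutes>`` (the batch is
the biological x technical replicate pair).  Writers prepend ``#``-prefixed
provenance lines (tool version, seed, thresholds, config hash) which readers
skip.
"""

from __future__ import annotations

import hashlib
import re
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .decay import IntensityMatrix

__all__ = [
    "MISSING",
    "membrane_id",
    "parse_membrane_id",
    "write_intensities",
    "read_intensities",
    "write_table",
    "read_table",
    "config_hash",
]

MISSING = "ND"
_MEMBRANE_RE = re.compile(r"^B(\d+)T(\d+)_t([0-9.]+)$")


def membrane_id(bio_rep: int, tech_rep: int, time_min: float) -> str:
    return f"B{bio_rep}T{tech_rep}_t{time_min:g}"


def parse_membrane_id(name: str) -> dict:
    m = _MEMBRANE_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse membrane column name {name!r}")
    bio, tech, t = int(m.group(1)), int(m.group(2)), float(m.group(3))
    return {"time_min": t, "bio_rep": bio, "tech_rep": tech,
            "batch": f"B{bio}T{tech}"}


def _provenance_lines(provenance: Mapping[str, object] | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {key}: {value}\n" for key, value in provenance.items())


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
    index: bool = True,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", na_rep=MISSING, index=index)
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                       na_values=[MISSING, "NA"], keep_default_na=True)


def write_intensities(
    matrix: IntensityMatrix,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> Path:
    df = matrix.values.copy()
    df.index.name = "gene"
    return write_table(df, path, provenance=provenance)


def read_intensities(path: str | Path) -> IntensityMatrix:
    values = read_table(path)
    meta = pd.DataFrame(
        [parse_membrane_id(c) for c in values.columns],
        index=pd.Index(list(values.columns), name="membrane"),
    )
    return IntensityMatrix(values=values, membranes=meta)


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for provenance headers."""
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
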