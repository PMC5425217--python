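"""File I/O: intensity tables, C_T tables, run configs, manifests, reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Optional

import pandas as pd

from .model import PopulationSample
from .stats import CtRecord

__all__ = ["read_intensity_csv", "write_intensity_csv", "read_ct_csv",
           "RunManifest", "load_run_config", "validate_report",
           "ReportValidationError"]


class ParseError(ValueError):
    pass


def read_intensity_csv(path) -> PopulationSample:
    """Read a per-cell intensity table (header: cell_id, protein[, mrna]).

    Non-numeric or negative entries are rejected with their row numbers
    (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "protein" not in cols:
        raise ParseError(f"{path}: missing required column 'protein'")
    bad: List[int] = []
    for col in ("protein", "mrna"):
        if col not in cols:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        mask = vals.isna() | (vals < 0)
        bad.extend((df.index[mask] + 2).tolist())
        df[col] = vals
    if bad:
        raise ParseError(
            f"{path}: non-numeric or negative intensities at rows "
            f"{sorted(set(bad))}")
    mrna = df["mrna"].to_numpy(float) if "mrna" in cols else None
    return PopulationSample(protein=df["protein"].to_numpy(float), mrna=mrna)


def write_intensity_csv(path, sample: PopulationSample) -> None:
    # 17 significant digits keep the round trip exact
    sample.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_ct_csv(path) -> List[CtRecord]:
    """Read qPCR cycle thresholds from a (sample, gene, ct) table with
    genes 'target' and 'housekeeping'."""
    df = pd.read_csv(path)
    need = {"sample", "gene", "ct"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(need)}")
    records = []
    for name, grp in df.groupby("sample", sort=False):
        by_gene = grp.set_index("gene")["ct"]
        try:
            records.append(CtRecord(sample=str(name),
                                    ct_target=float(by_gene["target"]),
                                    ct_housekeeping=float(
                                        by_gene["housekeeping"])))
        except KeyError as exc:
            raise ParseError(
                f"{path}: sample {name!r} missing gene {exc}") from None
    return records


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record: identical manifests imply identical outputs."""

    config_hash: str
    master_seed: int
    package_version: str
    input_digests: Dict[str, str] = field(default_factory=dict)
    created: str = ""

    @classmethod
    def build(cls, config: dict, master_seed: int,
              input_paths: Optional[Dict[str, str]] = None) -> "RunManifest":
        from . import __version__

        payload = json.dumps(config, sort_keys=True, default=str)
        return cls(
            config_hash=hashlib.sha256(payload.encode()).hexdigest(),
            master_seed=int(master_seed),
            package_version=__version__,
            input_digests={k: _digest(v) for k, v in
                           (input_paths or {}).items()},
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def load_run_config(path) -> dict:
    text = str(path)
    if text.endswith((".yml", ".yaml")):
        import yaml

        with open(path) as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# report schema (shipped as package data) and a minimal structural validator

class ReportValidationError(ValueError):
    pass


def _schema() -> dict:
    import importlib.resources as res

    with res.files("p53abc").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Check a report bundle against the shipped structural schema.

    Supports the subset of JSON-schema used there: type, required,
    properties, items.  Raises ReportValidationError on mismatch.
    """
    def check(node, schema, where):
        t = schema.get("type")
        if t == "object":
            if not isinstance(node, dict):
                raise ReportValidationError(f"{where}: expected object")
            for key in schema.get("required", []):
                if key not in node:
                    raise ReportValidationError(f"{where}: missing '{key}'")
            for key, sub in schema.get("properties", {}).items():
                if key in node:
                    check(node[key], sub, f"{where}.{key}")
        elif t == "array":
            if not isinstance(node, list):
                raise ReportValidationError(f"{where}: expected array")
            if "items" in schema:
                for i, item in enumerate(node):
                    check(item, schema["items"], f"{where}[{i}]")
        elif t == "number":
            if not isinstance(node, (int, float)) or isinstance(node, bool):
                raise ReportValidationError(f"{where}: expected number")
        elif t == "string":
            if not isinstance(node, str):
                raise ReportValidationError(f"{where}: expected string")

    check(report, _schema(), "report")
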