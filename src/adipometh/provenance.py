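"""Provenance records written next to every CLI artifact."""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

from pydantic import BaseModel, Field

from . import __version__


class Provenance(BaseModel):
    """What produced an output directory: command, config, inputs, counts."""

    command: str
    package_version: str = Field(default=__version__)
    python_version: str = Field(default_factory=lambda: sys.version.split()[0])
    config: dict = Field(default_factory=dict)
    input_checksums: dict[str, str] = Field(default_factory=dict)
    counts: dict[str, int] = Field(default_factory=dict)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(record: Provenance, path) -> None:
    Path(path).write_text(record.model_dump_json(indent=1))


def read_provenance(path) -> Provenance:
    return Provenance.model_validate_json(Path(path).read_text())


def export_schema(path) -> None:
    Path(path).write_text(json.dumps(Provenance.model_json_schema(), indent=1))
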