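"""Run manifests: reproducibility metadata written next to every CLI output.

A manifest records the canonical configuration (and its hash), the package
version, the seeds in play and an index of every file the run wrote.  Two
runs with identical manifests produce bit-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

__all__ = ["RunManifest"]


def _hash_obj(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: Dict[str, int] = field(default_factory=dict)
    outputs: List[str] = field(default_factory=list)
    version: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__

    @property
    def config_hash(self) -> str:
        return _hash_obj(self.config)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        path = Path(path)
        payload = {
            "command": self.command,
            "version": self.version,
            "config_hash": self.config_hash,
            "config": self.config,
            "seeds": self.seeds,
            "outputs": sorted(self.outputs),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        m = cls(command=data["command"], config=data["config"],
                seeds=data.get("seeds", {}), version=data.get("version", ""))
        m.outputs = data.get("outputs", [])
        return m
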