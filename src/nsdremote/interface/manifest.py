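"""Run manifest: reproducibility metadata written next to every output set."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


def config_hash(config: dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON form; stable under key
    reordering."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    package_version: str
    files: list[str] = field(default_factory=list)
    created: str = ""

    def __post_init__(self):
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "master_seed": self.master_seed,
            "package_version": self.package_version,
            "files": self.files,
            "created": self.created,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            config_hash=data["config_hash"],
            master_seed=data["master_seed"],
            package_version=data["package_version"],
            files=data["files"],
            created=data["created"],
        )

    def verify_files(self, root: str | Path) -> list[str]:
        """Return the subset of listed files missing under ``root``."""
        root = Path(root)
        return [f for f in self.files if not (root / f).exists()]
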