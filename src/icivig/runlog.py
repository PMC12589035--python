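"""Structured run log: JSON-lines bookkeeping of counts and exclusions.

Every pipeline stage appends entries of the form
``{"stage": ..., "event": ..., **counts}`` so that each number printed in
an output table can be traced back to a logged count.
"""

from __future__ import annotations

import json
from pathlib import Path


class RunLog:
    def __init__(self) -> None:
        self.entries: list[dict] = []

    def add(self, stage: str, event: str, **fields) -> None:
        entry = {"stage": stage, "event": event}
        entry.update(fields)
        self.entries.append(entry)

    def counts(self, stage: str | None = None) -> list[dict]:
        if stage is None:
            return list(self.entries)
        return [e for e in self.entries if e["stage"] == stage]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            for entry in self.entries:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")
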