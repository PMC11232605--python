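"""Shared plumbing: deterministic seed fan-out and atomic file writes."""

from __future__ import annotations

import hashlib
import os
import tempfile
from pathlib import Path

__all__ = ["child_seed", "atomic_write_text"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a named child seed from a master seed.

    Uses SHA-256 of "master:name" reduced below 2**31, so each module
    (and each epoch, split, ...) gets an independent, reproducible
    substream regardless of call order.
    """
    digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def atomic_write_text(path, text: str) -> None:
    """Write via a temporary file in the same directory, then rename, so
    a crash never leaves a half-written artifact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
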