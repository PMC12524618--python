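"""Download coordinate files from the wwPDB (network required).

Used by the spot checks against published survey entries; everything else
in the package works offline.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

__all__ = ["FetchError", "fetch_structure"]

_URL = "https://files.rcsb.org/download/{pdb_id}.{ext}"


class FetchError(RuntimeError):
    """The entry could not be downloaded (no network, or unknown id)."""


def fetch_structure(
    pdb_id: str,
    cache_dir: str | Path,
    format: str = "pdb",
    timeout: float = 20.0,
) -> Path:
    """Fetch one PDB entry into ``cache_dir``; cached files are reused."""
    pdb_id = pdb_id.upper()
    ext = {"pdb": "pdb", "mmcif": "cif"}[format.lower()]
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{pdb_id}.{ext}"
    if target.exists() and target.stat().st_size > 0:
        return target
    url = _URL.format(pdb_id=pdb_id, ext=ext)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(f"could not download {pdb_id} from {url}: {exc}") from exc
    target.write_bytes(data)
    return target
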