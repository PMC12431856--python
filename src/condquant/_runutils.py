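"""Seed derivation and manifest helpers shared by the CLI pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

__all__ = ["stage_seed", "sha256_file", "write_manifest"]


def stage_seed(master_seed: int, stage: str) -> int:
    """A per-stage seed derived by hashing the stage name with the master.

    Adding a stage never perturbs another stage's draws.  Result < 2**31.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: dict, seeds: dict,
                   artifacts: list) -> Path:
    """Write the reproducibility manifest for a run.

    Checksums cover every artifact (the manifest itself excluded), so two
    runs with the same config and master seed can be compared byte-for-byte.
    """
    import numpy, scipy, skimage, pandas

    outdir = Path(outdir)
    checksums = {
        str(Path(p).relative_to(outdir)): sha256_file(p)
        for p in sorted(map(str, artifacts))
    }
    manifest = {
        "config": config,
        "seeds": seeds,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pandas.__version__,
        },
        "checksums": checksums,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
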