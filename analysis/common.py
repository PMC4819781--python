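"""Shared plumbing for the numbered analysis drivers."""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from ratconn.io import Connectome, read_edge_list
from ratconn.synth import GroundTruth, generate

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "synthetic"


def parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=0,
                   help="generator / analysis seed (default 0)")
    p.add_argument("--nulls", type=int, default=200,
                   help="rewired nulls for normalization (default 200)")
    p.add_argument("--perms", type=int, default=2000,
                   help="label permutations per contrast (default 2000)")
    return p


def load_dataset(seed: int) -> tuple[Connectome, GroundTruth]:
    """Read the simulated dataset written by 01_simulate.py, or regenerate
    it deterministically from the seed if it is not on disk."""
    edges, regions, truth = (DATA / "edges.tsv", DATA / "regions.tsv",
                             DATA / "truth.json")
    if edges.exists() and regions.exists() and truth.exists():
        return read_edge_list(edges, regions), GroundTruth.from_json(truth)
    return generate(seed=seed)


def write_json(name: str, payload: dict) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return clean(obj.tolist())
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating, float)):
            return float(obj) if np.isfinite(obj) else None
        if isinstance(obj, np.bool_):
            return bool(obj)
        return obj

    path.write_text(json.dumps(clean(payload), indent=1))
    return path
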