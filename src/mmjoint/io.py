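"""File readers/writers: CSV matrices, Q-matrices, chain containers.

Matrices travel as labeled CSV (rows = persons, columns = items; empty
cell = missing).  Observed times that are zero or negative are coerced
to missing with a logged count, mirroring the empirical convention of
dropping zero response times while keeping the responses.  Chains are
stored in a self-describing ``.npz`` container: one named array per
parameter block plus a JSON metadata record (schema version, seeds,
config echo).
"""

from __future__ import annotations

import json
import logging
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .core import JointDataset, QMatrix
from .inference import PosteriorChains

__all__ = [
    "read_q_matrix",
    "write_q_matrix",
    "read_joint_dataset",
    "write_joint_dataset",
    "write_chains",
    "read_chains",
]

logger = logging.getLogger("mmjoint")

_CHAINS_SCHEMA = "mmjoint-chains-v1"


def read_q_matrix(path) -> QMatrix:
    """CSV with a header row of dimension labels and first column of item labels."""
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"malformed Q-matrix in {path}: entries must be 0/1")
    return QMatrix(vals.astype(np.int8),
                   item_ids=[str(i) for i in df.index],
                   dim_ids=[str(c) for c in df.columns])


def write_q_matrix(q: QMatrix, path) -> None:
    pd.DataFrame(q.entries, index=q.item_ids, columns=q.dim_ids).to_csv(path)


def read_joint_dataset(responses_path, times_path, q_path) -> JointDataset:
    """Assemble a dataset from aligned response/time CSVs and a Q-matrix.

    Row and column labels of the two matrices must agree with each other
    and with the Q-matrix item labels; mismatches are hard errors.
    """
    q = read_q_matrix(q_path)
    ydf = pd.read_csv(responses_path, index_col=0, float_precision="round_trip")
    tdf = pd.read_csv(times_path, index_col=0, float_precision="round_trip")
    if list(ydf.index) != list(tdf.index):
        raise ValueError("person labels of responses and times do not match")
    if list(ydf.columns) != list(tdf.columns):
        raise ValueError("item labels of responses and times do not match")
    if [str(c) for c in ydf.columns] != q.item_ids:
        raise ValueError("item labels do not match the Q-matrix")
    Y = ydf.to_numpy(dtype=float)
    T = tdf.to_numpy(dtype=float)
    obs_y = ~np.isnan(Y)
    bad_y = obs_y & ~np.isin(Y, (0.0, 1.0))
    if bad_y.any():
        n, i = np.argwhere(bad_y)[0]
        raise ValueError(
            f"non-binary response {Y[n, i]!r} at person {ydf.index[n]!r}, "
            f"item {ydf.columns[i]!r}")
    nonpos = (~np.isnan(T)) & (T <= 0)
    if nonpos.any():
        logger.info("coerced %d non-positive time(s) to missing", int(nonpos.sum()))
        T = np.where(nonpos, np.nan, T)
    data = JointDataset(Y, T, q, person_ids=[str(i) for i in ydf.index])
    data.n_coerced_times = int(nonpos.sum())
    return data


def write_joint_dataset(data: JointDataset, responses_path, times_path) -> None:
    cols = data.q.item_ids
    pd.DataFrame(data.Y, index=data.person_ids, columns=cols).to_csv(responses_path)
    pd.DataFrame(data.T, index=data.person_ids, columns=cols).to_csv(times_path)


def write_chains(chains: PosteriorChains, path) -> None:
    """Lossless serialization of draws plus metadata."""
    meta = {
        "schema": _CHAINS_SCHEMA,
        "variant": chains.variant,
        "config": chains.config,
        "seeds": chains.seeds,
        "acceptance": chains.acceptance,
        "draw_keys": sorted(chains.draws),
        "has_q_ability": chains.q_ability is not None,
    }
    arrays = {f"draws_{k}": v for k, v in chains.draws.items()}
    arrays["q_speed"] = chains.q_speed
    if chains.q_ability is not None:
        arrays["q_ability"] = chains.q_ability
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def read_chains(path) -> PosteriorChains:
    try:
        with np.load(path) as z:
            if "meta_json" not in z:
                raise ValueError(f"{path}: not a chains container (no metadata)")
            meta = json.loads(bytes(z["meta_json"].tobytes()).decode("utf-8"))
            if meta.get("schema") != _CHAINS_SCHEMA:
                raise ValueError(
                    f"{path}: schema {meta.get('schema')!r} != {_CHAINS_SCHEMA!r}")
            draws = {k: z[f"draws_{k}"] for k in meta["draw_keys"]}
            q_speed = z["q_speed"]
            q_ability = z["q_ability"] if meta["has_q_ability"] else None
    except (OSError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        raise ValueError(f"cannot read chains container {path}: {exc}") from exc
    return PosteriorChains(
        draws=draws, variant=meta["variant"], q_ability=q_ability,
        q_speed=q_speed, config=meta["config"], seeds=meta["seeds"],
        acceptance=meta["acceptance"])
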