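"""Readers and writers for datasets, Q-matrices, truth files and fits.

Datasets travel as long-format CSV (learner_id, time, item_id, response,
rt_seconds; learner/time/item identifiers are 1-based in files), the
Q-matrix as a separate CSV keyed by item_id, and simulation truth as JSON.
Fitted chains are persisted as an .npz bundle plus human-readable summary
and manifest files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sampler import STRUCTURAL_FIELDS, McmcConfig, McmcSamples
from .simulate import SimResult
from .types import DomainError, ItemParams, LatentState, ObservedData, PersonParams, QMatrix, StructuralParams

DATA_COLUMNS = ["learner_id", "time", "item_id", "response", "rt_seconds"]


def write_dataset(path, data: ObservedData) -> None:
    n, J = data.x.shape
    learner = np.repeat(np.arange(1, n + 1), J)
    item = np.tile(np.arange(1, J + 1), n)
    time = np.tile(data.item_time + 1, n)
    df = pd.DataFrame({
        "learner_id": learner, "time": time, "item_id": item,
        "response": data.x.ravel(), "rt_seconds": data.latency.ravel(),
    })
    df.to_csv(path, index=False)


def write_qmatrix(path, q: QMatrix) -> None:
    cols = {f"skill_{k + 1}": q.q[:, k] for k in range(q.n_skills)}
    pd.DataFrame({"item_id": np.arange(1, q.n_items + 1), **cols}).to_csv(path, index=False)


def read_qmatrix(path) -> QMatrix:
    df = pd.read_csv(path)
    if "item_id" not in df.columns:
        raise DomainError(f"{path}: Q-matrix CSV needs an item_id column")
    skills = [c for c in df.columns if c.startswith("skill_")]
    if not skills:
        raise DomainError(f"{path}: no skill_* columns found")
    df = df.sort_values("item_id")
    q = df[skills].to_numpy()
    bad = np.flatnonzero(~np.isin(q, (0, 1)).all(axis=1))
    if bad.size:
        raise DomainError(f"{path}: non-binary Q entries at rows {bad[:5] + 2}")
    return QMatrix(q)


def read_dataset(data_path, q_path) -> ObservedData:
    """Load and validate a long-format dataset + Q-matrix pair.

    Rejects missing columns, non-binary responses, non-positive response
    times (naming the offending rows), duplicate (learner, time, item)
    triplets, and items appearing at more than one time point.
    """
    q = read_qmatrix(q_path)
    df = pd.read_csv(data_path)
    missing = [c for c in DATA_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"{data_path}: missing columns {missing}")
    if df[DATA_COLUMNS[:4]].isna().any().any() or df["rt_seconds"].isna().any():
        raise DomainError(f"{data_path}: missing values are not supported")
    bad = np.flatnonzero(~df["response"].isin((0, 1)).to_numpy())
    if bad.size:
        raise DomainError(f"{data_path}: non-binary response at rows {bad[:5] + 2}")
    bad = np.flatnonzero(~(df["rt_seconds"].to_numpy() > 0))
    if bad.size:
        raise DomainError(f"{data_path}: non-positive rt_seconds at rows {bad[:5] + 2}")
    if df.duplicated(["learner_id", "item_id"]).any():
        rows = np.flatnonzero(df.duplicated(["learner_id", "item_id"]).to_numpy())
        raise DomainError(f"{data_path}: duplicate (learner, item) rows at {rows[:5] + 2}")
    item_map = df.groupby("item_id")["time"].nunique()
    if (item_map > 1).any():
        raise DomainError(f"{data_path}: items assigned to several time points: "
                          f"{item_map[item_map > 1].index.tolist()[:5]}")
    learners = np.sort(df["learner_id"].unique())
    items = np.sort(df["item_id"].unique())
    if items.size != q.n_items:
        raise DomainError(f"{data_path}: {items.size} items in data but "
                          f"{q.n_items} rows in the Q-matrix")
    li = {v: i for i, v in enumerate(learners)}
    ji = {v: j for j, v in enumerate(items)}
    n, J = learners.size, items.size
    x = np.full((n, J), -1, dtype=np.int64)
    lat = np.full((n, J), np.nan)
    rows_i = df["learner_id"].map(li).to_numpy()
    rows_j = df["item_id"].map(ji).to_numpy()
    x[rows_i, rows_j] = df["response"].to_numpy()
    lat[rows_i, rows_j] = df["rt_seconds"].to_numpy()
    if (x < 0).any():
        raise DomainError(f"{data_path}: incomplete learner x item grid "
                          "(missing responses are not supported)")
    time_of = df.groupby("item_id")["time"].first()
    item_time = time_of.loc[items].to_numpy().astype(np.int64) - 1
    return ObservedData(x=x, latency=lat, item_time=item_time, q=q)


def write_truth(path, sim: SimResult) -> None:
    st = sim.structural
    payload = {
        "seed": sim.seed,
        "structural": {k: float(getattr(st, k)) for k in STRUCTURAL_FIELDS},
        "pi": st.pi.tolist(),
        "item": {k: getattr(sim.item_params, k).tolist() for k in ("s", "g", "gamma", "a")},
        "theta": sim.person_params.theta.tolist(),
        "tau": sim.person_params.tau.tolist(),
        "alpha": sim.latent.alpha.tolist(),
        "d": sim.latent.d.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path, data: ObservedData) -> SimResult:
    p = json.loads(Path(path).read_text())
    st = StructuralParams(pi=np.array(p["pi"]), **p["structural"])
    items = ItemParams(**{k: np.array(v) for k, v in p["item"].items()})
    latent = LatentState(alpha=np.array(p["alpha"], dtype=np.int8),
                         d=np.array(p["d"], dtype=np.int8))
    persons = PersonParams(theta=np.array(p["theta"]), tau=np.array(p["tau"]))
    return SimResult(data=data, latent=latent, item_params=items,
                     person_params=persons, structural=st, seed=p["seed"])


def save_fit(path, chains: list[McmcSamples]) -> None:
    """Persist chains (traces, frequencies, snapshots) to one .npz bundle."""
    arrays = {"n_chains": np.array(len(chains))}
    for ci, c in enumerate(chains):
        p = f"c{ci}_"
        for k, v in c.structural.items():
            arrays[p + "structural_" + k] = v
        arrays[p + "pi"] = c.pi
        for k, v in c.item.items():
            arrays[p + "item_" + k] = v
        for k, v in c.person.items():
            arrays[p + "person_" + k] = v
        arrays[p + "deviance"] = c.deviance
        arrays[p + "alpha_freq"] = c.alpha_freq
        arrays[p + "d_freq"] = c.d_freq
        arrays[p + "burn"] = np.array(c.burn)
        arrays[p + "n_snapshots"] = np.array(len(c.snapshots))
        for si, snap in enumerate(c.snapshots):
            for k, v in snap.items():
                arrays[f"{p}snap{si}_{k}"] = np.asarray(v)
    np.savez_compressed(path, **arrays)


def load_fit(path) -> list[McmcSamples]:
    z = np.load(path)
    chains = []
    for ci in range(int(z["n_chains"])):
        p = f"c{ci}_"
        structural = {k: z[p + "structural_" + k] for k in STRUCTURAL_FIELDS}
        item = {k: z[p + "item_" + k] for k in ("s", "g", "gamma", "a")}
        person = {k: z[p + "person_" + k] for k in ("theta", "tau")
                  if p + "person_" + k in z}
        snaps = []
        for si in range(int(z[p + "n_snapshots"])):
            snap = {}
            for k in ("cls", "d", "tau", "s", "g", "gamma", "a",
                      "gstar", "mu1", "sigma1_sq", "phi"):
                v = z[f"{p}snap{si}_{k}"]
                snap[k] = float(v) if v.ndim == 0 else v
            snaps.append(snap)
        burn = int(z[p + "burn"])
        chains.append(McmcSamples(
            structural=structural, pi=z[p + "pi"], item=item, person=person,
            deviance=z[p + "deviance"], alpha_freq=z[p + "alpha_freq"],
            d_freq=z[p + "d_freq"], snapshots=snaps, burn=burn, seed=None,
            acceptance={}, config=McmcConfig(draws=len(z[p + "deviance"]), burn=burn)))
    return chains
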