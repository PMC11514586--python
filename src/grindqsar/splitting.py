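"""Training/test partitioning stratified by activity quantile and cluster.

The split mirrors common 3D-QSAR practice: test compounds are drawn so that
(a) the whole activity range is represented in both sets, (b) every
structural cluster with at least two members contributes to both sets, and
(c) no test compound extrapolates beyond the training activity range (the
global activity minimum and maximum are always assigned to training).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class Split:
    train_ids: list[str]
    test_ids: list[str]
    strata: pd.DataFrame  # cell counts: cluster x activity quantile x set

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out["set"] = np.where(out["id"].isin(self.test_ids), "test", "train")
        return out


def make_split(table: pd.DataFrame, n_test: int, seed: int,
               n_quantiles: int = 5) -> Split:
    """Stratified train/test split over activity-quantile x cluster cells.

    ``table`` needs columns ``id``, ``pIC50`` and ``cluster``.  Deterministic
    given ``seed``; test slots are allocated to cells by largest remainder
    and drawn without replacement.
    """
    n = len(table)
    if not 0 < n_test < n:
        raise ValueError("n_test must be positive and smaller than the dataset")
    rng = np.random.default_rng(seed)
    df = table.reset_index(drop=True).copy()
    df["id"] = df["id"].astype(str)
    act = df["pIC50"].to_numpy(dtype=float)

    forced_train = {df.loc[int(np.argmin(act)), "id"],
                    df.loc[int(np.argmax(act)), "id"]}
    cluster_sizes = df["cluster"].value_counts()
    for cl, size in cluster_sizes.items():
        if size == 1:
            cid = df.loc[df["cluster"] == cl, "id"].iloc[0]
            forced_train.add(cid)
            log.info("cluster %s has a single member (%s): assigned to training",
                     cl, cid)

    q = min(n_quantiles, max(1, n // 3))
    df["quantile"] = pd.qcut(df["pIC50"], q, labels=False, duplicates="drop")

    eligible = df[~df["id"].isin(forced_train)]
    cells = eligible.groupby(["cluster", "quantile"], observed=True)
    keys, sizes = zip(*[(k, len(g)) for k, g in cells])
    quota = n_test * np.array(sizes) / len(eligible)
    base = np.floor(quota).astype(int)
    base = np.minimum(base, sizes)
    shortfall = n_test - base.sum()
    remainders = quota - np.floor(quota)
    for j in np.argsort(-remainders):
        if shortfall <= 0:
            break
        if base[j] < sizes[j]:
            base[j] += 1
            shortfall -= 1
    # if still short (small cells), fill greedily from cells with headroom
    j = 0
    order = np.argsort(-np.array(sizes))
    while shortfall > 0 and j < len(order):
        k = order[j]
        room = sizes[k] - base[k]
        take = min(room, shortfall)
        base[k] += take
        shortfall -= take
        j += 1

    test_ids: list[str] = []
    for (key, g), n_cell in zip(cells, base):
        if n_cell > 0:
            pick = rng.choice(g["id"].to_numpy(), size=n_cell, replace=False)
            test_ids.extend(pick.tolist())

    # every multi-member cluster must appear in both sets
    for cl, size in cluster_sizes.items():
        if size < 2:
            continue
        members = set(df.loc[df["cluster"] == cl, "id"])
        cl_test = members & set(test_ids)
        if not cl_test and len(test_ids) > 0:
            candidates = sorted((members - forced_train))
            if not candidates:
                continue
            donor_cluster = df[df["id"].isin(test_ids)]["cluster"].value_counts().idxmax()
            donor_ids = [t for t in test_ids
                         if df.loc[df["id"] == t, "cluster"].iloc[0] == donor_cluster]
            removed = donor_ids[int(rng.integers(len(donor_ids)))]
            test_ids.remove(removed)
            test_ids.append(str(rng.choice(candidates)))
        elif cl_test == members:
            moved = str(rng.choice(sorted(cl_test)))
            test_ids.remove(moved)
            extra = eligible[~eligible["id"].isin(test_ids)]
            extra = extra[extra["cluster"] != cl]
            if len(extra):
                test_ids.append(str(rng.choice(extra["id"].to_numpy())))

    test_set = set(test_ids)
    train_ids = [cid for cid in df["id"] if cid not in test_set]
    df["set"] = np.where(df["id"].isin(test_set), "test", "train")
    strata = (df.groupby(["cluster", "quantile", "set"], observed=True)
              .size().rename("count").reset_index())
    return Split(train_ids=train_ids, test_ids=sorted(test_set), strata=strata)
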