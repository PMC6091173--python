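"""Pedigree container and I/O.

A pedigree is a topologically ordered table of animals with sire/dam
references, a birth cohort (generation or year) and a genotyped flag.
Unknown parents are coded 0 in external files; internally parents are
0-based positional indices with -1 for unknown.  Founders are the rows
with both parents unknown; their count ``F`` is the quantity entering the
metafounder algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters
    ----------
    ids
        External animal identifiers (any hashable scalar), in pedigree order.
    sire, dam
        0-based positional indices into ``ids``; ``-1`` for unknown.
    cohort
        Integer birth cohort (generation number or birth year) per animal.
    sex
        Optional; 0 = male, 1 = female, -1 = unknown.
    genotyped
        Boolean flag per animal.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    cohort: np.ndarray
    sex: np.ndarray | None = None
    genotyped: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.cohort = np.asarray(self.cohort, dtype=np.int64)
        if self.sex is not None:
            self.sex = np.asarray(self.sex, dtype=np.int64)
        if self.genotyped is None:
            self.genotyped = np.zeros(self.n, dtype=bool)
        else:
            self.genotyped = np.asarray(self.genotyped, dtype=bool)
        self._index = {a: i for i, a in enumerate(self.ids.tolist())}
        if len(self._index) != self.n:
            raise ValueError("duplicate animal ids in pedigree")
        self.validate()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    @property
    def n_founders(self) -> int:
        """Number of founders F (both parents unknown)."""
        return int(self.is_founder.sum())

    def positions(self, ids) -> np.ndarray:
        """Positional indices of external ids (raises on unknown id)."""
        try:
            return np.array([self._index[a] for a in np.asarray(ids).tolist()],
                            dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"id {e.args[0]!r} not in pedigree") from None

    def validate(self) -> None:
        """Check topological order: every parent precedes its offspring."""
        idx = np.arange(self.n)
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            known = par != UNKNOWN
            if np.any(par[known] < 0) or np.any(par[known] >= self.n):
                bad = int(np.where(known & ((par < 0) | (par >= self.n)))[0][0])
                raise ValueError(f"row {bad}: {name} index out of range")
            if np.any(par[known] >= idx[known]):
                bad = int(np.where(known & (par >= idx))[0][0])
                raise ValueError(
                    f"pedigree not topologically ordered: row {bad} "
                    f"(id {self.ids[bad]!r}) has {name} at or after itself")

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        """External representation: parent ids with 0 for unknown."""
        def ext(par):
            out = np.zeros(self.n, dtype=object)
            known = par != UNKNOWN
            out[known] = self.ids[par[known]]
            return out

        df = pd.DataFrame({
            "id": self.ids,
            "sire": ext(self.sire),
            "dam": ext(self.dam),
            "sex": self.sex if self.sex is not None else -1,
            "generation": self.cohort,
        })
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        ids = df["id"].to_numpy()
        index = {a: i for i, a in enumerate(ids.tolist())}

        def internal(col):
            out = np.full(len(df), UNKNOWN, dtype=np.int64)
            for i, v in enumerate(df[col].tolist()):
                if v != 0 and not pd.isna(v):
                    out[i] = index[v]
            return out

        return cls(
            ids=ids,
            sire=internal("sire"),
            dam=internal("dam"),
            cohort=df["generation"].to_numpy()
            if "generation" in df else np.zeros(len(df), dtype=np.int64),
            sex=df["sex"].to_numpy() if "sex" in df else None,
        )

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path))
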