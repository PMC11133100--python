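"""Binary response data container.

Persons-by-items matrices of dichotomous (0/1) responses with an explicit
missingness mask.  Missing responses are assumed missing at random (MAR) and
contribute nothing to the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix"]


@dataclass
class ResponseMatrix:
    """Persons x items binary responses with missingness mask.

    Parameters
    ----------
    values : ndarray of shape (n_persons, n_items), float
        Entries 0.0, 1.0 or NaN (missing).
    person_ids : sequence of unique person identifiers, length n_persons.
    item_names : sequence of unique item names, length n_items.
    """

    values: np.ndarray
    person_ids: list = field(default_factory=list)
    item_names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D persons x items matrix")
        n, j = self.values.shape
        if n < 1 or j < 1:
            raise ValueError("need at least one person and one item")
        if not self.person_ids:
            self.person_ids = list(range(1, n + 1))
        if not self.item_names:
            self.item_names = [f"y{k}" for k in range(1, j + 1)]
        self.person_ids = list(self.person_ids)
        self.item_names = [str(s) for s in self.item_names]
        if len(self.person_ids) != n:
            raise ValueError("person_ids length does not match values")
        if len(self.item_names) != j:
            raise ValueError("item_names length does not match values")
        if len(set(self.person_ids)) != n:
            raise ValueError("duplicate person ids")
        if len(set(self.item_names)) != j:
            raise ValueError("duplicate item names")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.all((obs == 0) | (obs == 1)):
            raise ValueError("non-missing entries must be 0 or 1")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the response is observed."""
        return ~np.isnan(self.values)

    def constant_items(self) -> list[str]:
        """Names of items with no observed variability (all 0 or all 1).

        Such items carry no information about their slope and make the model
        inestimable; callers must drop them explicitly before fitting.
        """
        out = []
        for k, name in enumerate(self.item_names):
            col = self.values[:, k]
            col = col[~np.isnan(col)]
            if col.size == 0 or np.all(col == col[0] if col.size else True):
                if col.size == 0 or col.min() == col.max():
                    out.append(name)
        return out

    def drop_items(self, names) -> "ResponseMatrix":
        keep = [k for k, n in enumerate(self.item_names) if n not in set(names)]
        return ResponseMatrix(
            self.values[:, keep],
            person_ids=self.person_ids,
            item_names=[self.item_names[k] for k in keep],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str | None = None) -> "ResponseMatrix":
        df = df.copy()
        if id_column is not None:
            if id_column not in df.columns:
                raise ValueError(f"id column {id_column!r} not found")
            ids = df[id_column].tolist()
            df = df.drop(columns=[id_column])
        else:
            ids = list(range(1, len(df) + 1))
        vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        # cells that were non-numeric text (not NA in the original) are invalid
        bad = np.isnan(vals) & df.notna().to_numpy()
        if bad.any():
            raise ValueError("non-binary cell value in response columns")
        return cls(vals, person_ids=ids, item_names=list(df.columns))

    def to_dataframe(self, id_column: str = "id") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_names)
        df.insert(0, id_column, self.person_ids)
        return df
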