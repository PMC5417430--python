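"""The assembled design matrix shared by all estimators."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

INTERCEPT = "const"
INTERACTION_SEP = ":"


def interaction_name(a: str, b: str) -> str:
    return f"{a}{INTERACTION_SEP}{b}"


def interaction_parents(name: str) -> tuple[str, str] | None:
    """Parse 'a:b' interaction column names; None for plain columns."""
    if INTERACTION_SEP in name:
        a, b = name.split(INTERACTION_SEP, 1)
        return a, b
    return None


@dataclass
class DesignMatrix:
    """Covariate matrix X (incl. intercept, interactions, region dummies) and
    fractional response y in [0, 1].

    ``region_block`` indexes the dummy columns; interaction columns are named
    ``parent_a:parent_b`` and must equal the elementwise product of their
    parents.
    """

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    region_block: list[int] = field(default_factory=list)
    response_name: str = "y"
    spec_name: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if len(self.y) != n:
            raise ValueError("X and y have inconsistent lengths")
        if len(self.column_names) != p:
            raise ValueError("column_names length must equal number of columns")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("design matrix contains missing or non-finite entries")
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("y must be a fraction in [0, 1]")
        if p >= n:
            raise ValueError(f"more parameters ({p}) than observations ({n})")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.column_index(name)]

    def column_index(self, name: str) -> int:
        try:
            return self.column_names.index(name)
        except ValueError:
            raise KeyError(f"column {name!r} not in design matrix") from None

    def interactions_of(self, var: str) -> list[tuple[str, str]]:
        """Interaction columns having ``var`` as a parent, with the partner name."""
        out = []
        for name in self.column_names:
            parents = interaction_parents(name)
            if parents and var in parents:
                partner = parents[1] if parents[0] == var else parents[0]
                out.append((name, partner))
        return out

    def subset(self, rows: np.ndarray) -> "DesignMatrix":
        return DesignMatrix(
            X=self.X[rows],
            y=self.y[rows],
            column_names=list(self.column_names),
            region_block=list(self.region_block),
            response_name=self.response_name,
            spec_name=self.spec_name,
        )

    def drop_columns(self, names: list[str]) -> "DesignMatrix":
        keep = [i for i, c in enumerate(self.column_names) if c not in names]
        kept_names = [self.column_names[i] for i in keep]
        region = [kept_names.index(self.column_names[i]) for i in self.region_block
                  if self.column_names[i] in kept_names]
        return DesignMatrix(
            X=self.X[:, keep],
            y=self.y,
            column_names=kept_names,
            region_block=region,
            response_name=self.response_name,
            spec_name=self.spec_name,
        )
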