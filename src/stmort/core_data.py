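"""Domain containers for areal space-time mortality panels.

The panel holds monthly death counts ``y_it`` for ``I`` areas over ``T``
consecutive months together with the elderly-population offset ``N_it``,
one particulate-matter exposure series, three meteorological covariates
and a static area-level deprivation index.  The adjacency graph encodes
district contiguity and underlies both the CAR priors and the spatial
weight matrices used for Moran's I.

Canonical indexing: areas are 0-based in sorted-label order, months are
0-based chronological.  Matrices are ``I x T`` (area-major); whenever a
panel is flattened, C order (cell ``(i, t) -> i*T + t``) is used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CAUSE_LABELS = ("total", "cardiovascular", "respiratory")
POLLUTANT_LABELS = ("PM10", "PM25")
WEIGHT_SCHEMES = ("binary", "row_standardized", "globally_standardized")

#: default long-format column names understood by :func:`read_panel`
DEFAULT_SCHEMA: Mapping[str, str] = {
    "area": "area",
    "month": "month",
    "deaths": "deaths",
    "population": "population",
    "pollutant": "pollutant",
    "temperature": "temperature",
    "humidity": "humidity",
    "wind": "wind",
    "deprivation": "deprivation",
}


class PanelValidationError(ValueError):
    """Raised when a panel violates its invariants."""


class SchemaError(KeyError):
    """Raised when a required column is missing from an input table."""


class AdjacencyError(ValueError):
    """Raised for malformed adjacency structures."""


@dataclass
class SpaceTimePanel:
    """Areal monthly panel of deaths, offsets and covariates."""

    area_ids: list
    month_index: list
    deaths: np.ndarray          # I x T, nonnegative integers
    offset_pop: np.ndarray      # I x T, positive integers (population >= 65)
    pollutant: np.ndarray       # I x T, ug/m3
    temperature: np.ndarray     # I x T, degrees C
    humidity: np.ndarray        # I x T, percent
    wind: np.ndarray            # I x T, m/s
    deprivation: np.ndarray     # length I, unitless index
    cause_label: str = "total"
    pollutant_label: str = "PM25"

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths)
        self.offset_pop = np.asarray(self.offset_pop)
        for name in ("pollutant", "temperature", "humidity", "wind"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.deprivation = np.asarray(self.deprivation, dtype=float)
        self.validate()

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_months(self) -> int:
        return len(self.month_index)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_areas, self.n_months)

    def validate(self) -> None:
        I, T = self.shape
        for name in ("deaths", "offset_pop", "pollutant", "temperature",
                     "humidity", "wind"):
            arr = getattr(self, name)
            if arr.shape != (I, T):
                raise PanelValidationError(
                    f"{name} has shape {arr.shape}, expected {(I, T)}")
            if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
                raise PanelValidationError(f"{name} contains non-finite cells")
        if self.deprivation.shape != (I,):
            raise PanelValidationError(
                f"deprivation has shape {self.deprivation.shape}, expected ({I},)")
        deaths_f = np.asarray(self.deaths, dtype=float)
        if np.any(deaths_f != np.round(deaths_f)) or np.any(deaths_f < 0):
            bad = np.argwhere((deaths_f != np.round(deaths_f)) | (deaths_f < 0))[0]
            raise PanelValidationError(
                f"deaths must be nonnegative integers; offending cell "
                f"(area={self.area_ids[bad[0]]}, month={self.month_index[bad[1]]})")
        self.deaths = np.round(deaths_f).astype(np.int64)
        pop_f = np.asarray(self.offset_pop, dtype=float)
        if np.any(pop_f < 1):
            bad = np.argwhere(pop_f < 1)[0]
            raise PanelValidationError(
                f"offset_pop must be >= 1; offending cell "
                f"(area={self.area_ids[bad[0]]}, month={self.month_index[bad[1]]})")
        self.offset_pop = np.round(pop_f).astype(np.int64)
        if np.any((self.humidity < 0) | (self.humidity > 100)):
            raise PanelValidationError("humidity outside [0, 100]")
        if np.any(self.wind < 0):
            raise PanelValidationError("negative wind speed")
        if self.cause_label not in CAUSE_LABELS:
            raise PanelValidationError(
                f"cause_label must be one of {CAUSE_LABELS}, got {self.cause_label!r}")
        if self.pollutant_label not in POLLUTANT_LABELS:
            raise PanelValidationError(
                f"pollutant_label must be one of {POLLUTANT_LABELS}, "
                f"got {self.pollutant_label!r}")

    def to_long(self, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Long-format DataFrame, one row per (area, month)."""
        schema = dict(DEFAULT_SCHEMA if schema is None else schema)
        I, T = self.shape
        area = np.repeat(self.area_ids, T)
        month = np.tile(self.month_index, I)
        return pd.DataFrame({
            schema["area"]: area,
            schema["month"]: month,
            schema["deaths"]: self.deaths.ravel(),
            schema["population"]: self.offset_pop.ravel(),
            schema["pollutant"]: self.pollutant.ravel(),
            schema["temperature"]: self.temperature.ravel(),
            schema["humidity"]: self.humidity.ravel(),
            schema["wind"]: self.wind.ravel(),
            schema["deprivation"]: np.repeat(self.deprivation, T),
        })

    def subset_months(self, months: Sequence[int]) -> "SpaceTimePanel":
        """Panel restricted to the given month positions (chronological)."""
        months = list(months)
        return SpaceTimePanel(
            area_ids=list(self.area_ids),
            month_index=[self.month_index[t] for t in months],
            deaths=self.deaths[:, months],
            offset_pop=self.offset_pop[:, months],
            pollutant=self.pollutant[:, months],
            temperature=self.temperature[:, months],
            humidity=self.humidity[:, months],
            wind=self.wind[:, months],
            deprivation=self.deprivation,
            cause_label=self.cause_label,
            pollutant_label=self.pollutant_label,
        )


@dataclass
class AdjacencyGraph:
    """Symmetric areal contiguity graph as per-area neighbor lists."""

    n_areas: int
    neighbor_lists: list

    def __post_init__(self) -> None:
        self.neighbor_lists = [sorted(int(j) for j in nbrs)
                               for nbrs in self.neighbor_lists]
        self.validate()

    def validate(self) -> None:
        if len(self.neighbor_lists) != self.n_areas:
            raise AdjacencyError("neighbor_lists length != n_areas")
        for i, nbrs in enumerate(self.neighbor_lists):
            for j in nbrs:
                if not 0 <= j < self.n_areas:
                    raise AdjacencyError(f"neighbor index {j} of area {i} out of range")
                if j == i:
                    raise AdjacencyError(f"self-loop at area {i}")
                if i not in self.neighbor_lists[j]:
                    raise AdjacencyError(
                        f"asymmetric adjacency: {i} lists {j} but {j} does not list {i}")

    @property
    def n_neighbors(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbor_lists], dtype=np.int64)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges (i < j)."""
        return [(i, j) for i, nbrs in enumerate(self.neighbor_lists)
                for j in nbrs if i < j]

    def isolated_areas(self) -> list[int]:
        return [i for i, n in enumerate(self.neighbor_lists) if not n]

    def adjacency_matrix(self):
        """Sparse CSR 0/1 adjacency matrix."""
        from scipy import sparse
        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbor_lists):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs)
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(self.n_areas, self.n_areas))

    def is_connected(self) -> bool:
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges())
        return nx.is_connected(g)

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper coloring; returns index arrays per color class.

        Nodes within a class are mutually non-adjacent, hence conditionally
        independent under a pairwise Markov random field on this graph.
        """
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges())
        colors = nx.coloring.greedy_color(g, strategy="largest_first")
        n_colors = max(colors.values()) + 1 if colors else 1
        return [np.array(sorted(i for i, c in colors.items() if c == k),
                         dtype=np.int64)
                for k in range(n_colors)]


@dataclass
class MCMCSettings:
    """Multi-chain Metropolis-within-Gibbs protocol.

    Defaults follow the reference protocol of two parallel chains keeping
    2500 thinned (by 50) draws each after burn-in.
    """

    n_chains: int = 2
    burn_in: int = 5000
    n_keep: int = 2500
    thin: int = 50
    seeds: tuple | None = None
    adapt_window: int = 50
    target_accept: float = 0.35

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 (Gelman-Rubin needs 2 chains)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.seeds is not None:
            self.seeds = tuple(int(s) for s in self.seeds)
            if len(set(self.seeds)) != len(self.seeds):
                raise ValueError("chain seeds must be distinct")
            if len(self.seeds) != self.n_chains:
                raise ValueError("need one seed per chain")

    def resolve_seeds(self, seed: int | None = None) -> tuple:
        """Per-chain seeds: explicit ones, else spawned from ``seed``."""
        if self.seeds is not None:
            return self.seeds
        base = 0 if seed is None else int(seed)
        ss = np.random.SeedSequence(base)
        return tuple(int(s.generate_state(1)[0] % (2**31 - 1))
                     for s in ss.spawn(self.n_chains))


@dataclass
class ModelConfig:
    """Priors, spline and interaction settings shared by all model stages."""

    coef_prior_variance: float = 1_000_000.0
    hyper_sd_upper: float = 10.0
    spline_df: tuple = (3, 2, 3)        # (temperature, humidity, wind)
    interaction_type: str = "III"
    zero_count_correction: float = 0.5
    ar1_rho_bounds: tuple = (0.0, 1.0)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        if self.coef_prior_variance <= 0:
            raise ValueError("coef_prior_variance must be > 0")
        if self.hyper_sd_upper <= 0:
            raise ValueError("hyper_sd_upper must be > 0")
        self.spline_df = tuple(int(d) for d in self.spline_df)
        if len(self.spline_df) != 3 or any(d < 1 for d in self.spline_df):
            raise ValueError("spline_df must be three integers >= 1")
        if self.interaction_type not in ("I", "II", "III", "IV"):
            raise ValueError(
                f"interaction_type must be one of I, II, III, IV; "
                f"got {self.interaction_type!r}")
        if not 0 < self.zero_count_correction <= 1:
            raise ValueError("zero_count_correction must lie in (0, 1]")
        lo, hi = self.ar1_rho_bounds
        if not -1 <= lo < hi <= 1:
            raise ValueError("ar1_rho_bounds must be an interval within [-1, 1]")
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCSettings(**self.mcmc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spline_df"] = list(self.spline_df)
        d["ar1_rho_bounds"] = list(self.ar1_rho_bounds)
        if d["mcmc"].get("seeds") is not None:
            d["mcmc"]["seeds"] = list(d["mcmc"]["seeds"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "mcmc" in d and isinstance(d["mcmc"], Mapping):
            d["mcmc"] = MCMCSettings(**d["mcmc"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_panel(path, schema: Mapping[str, str] | None = None,
               cause_label: str = "total",
               pollutant_label: str = "PM25") -> SpaceTimePanel:
    """Read a long-format comma-separated panel into a validated container.

    One row per (area, month); areas are sorted by label and months
    chronologically (by sorted label) to fix the canonical ordering.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    df = pd.read_csv(path)
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"panel file is missing column(s): {missing}")
    a, m = schema["area"], schema["month"]
    area_ids = sorted(df[a].unique().tolist())
    month_index = sorted(df[m].unique().tolist())
    I, T = len(area_ids), len(month_index)
    if len(df) != I * T or df.duplicated([a, m]).any():
        counts = df.groupby(a)[m].nunique()
        ragged = counts[counts != T]
        raise PanelValidationError(
            f"ragged panel: expected {I}x{T} complete grid; "
            f"areas with missing/duplicate months: {ragged.index.tolist()[:5]}")
    df = df.sort_values([a, m], kind="mergesort")

    def grid(col):
        return df[col].to_numpy().reshape(I, T)

    dep_grid = grid(schema["deprivation"]).astype(float)
    if not np.allclose(dep_grid, dep_grid[:, [0]], equal_nan=False):
        raise PanelValidationError("deprivation varies within an area")
    return SpaceTimePanel(
        area_ids=area_ids,
        month_index=month_index,
        deaths=grid(schema["deaths"]),
        offset_pop=grid(schema["population"]),
        pollutant=grid(schema["pollutant"]).astype(float),
        temperature=grid(schema["temperature"]).astype(float),
        humidity=grid(schema["humidity"]).astype(float),
        wind=grid(schema["wind"]).astype(float),
        deprivation=dep_grid[:, 0],
        cause_label=cause_label,
        pollutant_label=pollutant_label,
    )


def write_panel(panel: SpaceTimePanel, path,
                schema: Mapping[str, str] | None = None) -> None:
    """Write the panel in the long CSV format read by :func:`read_panel`."""
    panel.to_long(schema).to_csv(path, index=False)


def read_adjacency(path) -> tuple[AdjacencyGraph, list[str]]:
    """Read a GAL-style adjacency list.

    Format: a header line with the number of areas, then for each area a
    line ``<label> <neighbor count>`` followed by a line with the neighbor
    labels (empty if none).  Returns the graph plus warnings (one per
    isolated area); asymmetry and self-loops raise :class:`AdjacencyError`.
    """
    with open(path, encoding="utf-8") as fh:
        tokens_by_line = [line.split() for line in fh
                          if line.strip() and not line.startswith("#")]
    if not tokens_by_line:
        raise AdjacencyError("empty adjacency file")
    n = int(tokens_by_line[0][0])
    labels, raw_nbrs = [], []
    pos = 1
    for _ in range(n):
        if pos >= len(tokens_by_line):
            raise AdjacencyError("truncated adjacency file")
        header = tokens_by_line[pos]
        label, count = header[0], int(header[1])
        if count == 0:
            nbrs = []
            pos += 1
        else:
            if pos + 1 >= len(tokens_by_line):
                raise AdjacencyError(f"missing neighbor line for area {label}")
            nbrs = tokens_by_line[pos + 1]
            if len(nbrs) != count:
                raise AdjacencyError(
                    f"area {label} declares {count} neighbors but lists {len(nbrs)}")
            pos += 2
        labels.append(label)
        raw_nbrs.append(nbrs)
    order = sorted(range(n), key=lambda i: labels[i])
    index = {labels[i]: rank for rank, i in enumerate(order)}
    neighbor_lists: list[list[int]] = [[] for _ in range(n)]
    for rank, i in enumerate(order):
        for lab in raw_nbrs[i]:
            if lab not in index:
                raise AdjacencyError(f"unknown neighbor label {lab!r} for area {labels[i]}")
            if index[lab] == rank:
                raise AdjacencyError(f"self-loop at area {labels[i]}")
            neighbor_lists[rank].append(index[lab])
    for i, nbrs in enumerate(neighbor_lists):
        for j in nbrs:
            if i not in neighbor_lists[j]:
                li = sorted(index, key=index.get)
                raise AdjacencyError(
                    f"asymmetric adjacency between areas {li[i]} and {li[j]}")
    graph = AdjacencyGraph(n_areas=n, neighbor_lists=neighbor_lists)
    warnings = [f"area {sorted(index, key=index.get)[i]} has no neighbors"
                for i in graph.isolated_areas()]
    return graph, warnings


def write_adjacency(graph: AdjacencyGraph, path, labels=None) -> None:
    labels = list(range(graph.n_areas)) if labels is None else list(labels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{graph.n_areas}\n")
        for i, nbrs in enumerate(graph.neighbor_lists):
            fh.write(f"{labels[i]} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(str(labels[j]) for j in nbrs) + "\n")


def weight_matrix(graph: AdjacencyGraph, scheme: str) -> np.ndarray:
    """Spatial weight matrix under one of three standardizations.

    ``binary``: w_ij = 1 iff adjacent.  ``row_standardized``: each row of
    the binary matrix divided by its row sum.  ``globally_standardized``:
    the binary matrix divided by the mean of its row sums.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"scheme must be one of {WEIGHT_SCHEMES}, got {scheme!r}")
    W = graph.adjacency_matrix().toarray()
    if scheme == "binary":
        return W
    row_sums = W.sum(axis=1)
    if scheme == "row_standardized":
        if np.any(row_sums == 0):
            raise AdjacencyError(
                f"row standardization undefined for isolated areas "
                f"{graph.isolated_areas()}")
        return W / row_sums[:, None]
    return W / row_sums.mean()
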