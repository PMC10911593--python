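"""Scenario configuration schema: validated YAML descriptions of model runs.

A scenario file fully determines a run: which model, its rate parameters,
the habitat block (capacities or explicit density-dependent death rates),
how habitats are coupled (an explicit migration matrix, a uniform scalar
coefficient, or a dispersal kernel plus geometry), the initial populations,
and optionally which experiment driver to run.  Unknown keys are rejected so
that a typo cannot silently change a run, and every constraint is checked at
load time with an error naming the offending field.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from wolbnet.dispersal import (
    DispersalKernel,
    make_kernel,
    migration_matrix,
    positions_to_distances,
)
from wolbnet.model1 import Model1Params, validate_params
from wolbnet.model2 import Model2Params
from wolbnet.network import HabitatNetwork

__all__ = ["Scenario", "SchemaError", "load_scenario", "save_scenario"]

logger = logging.getLogger("wolbnet")

_TOP_KEYS = {"model", "note", "params", "habitats", "migration", "initial", "pde", "experiment"}
_MODELS = {"model1", "model2", "pde"}
_MIGRATION_KEYS = {"m", "matrix", "kernel", "distances", "positions"}
_KERNEL_KEYS = {"family", "xi", "sigma", "t", "q", "parameterization"}
_HABITAT_KEYS = {"K", "d"}
_PDE_KEYS = {"extent", "nodes", "D", "boundary"}


class SchemaError(ValueError):
    """A scenario file violates the schema; the message names the field."""


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    if not isinstance(block, dict):
        raise SchemaError(f"{where}: expected a mapping, got {type(block).__name__}")
    unknown = set(block) - allowed
    if unknown:
        raise SchemaError(f"{where}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


@dataclass
class Scenario:
    """A validated scenario description.

    Use :meth:`model1_params` / :meth:`model2_params`, :meth:`network`,
    :meth:`kernel`, :meth:`initial_model1` / :meth:`initial_model2` to
    materialize the domain objects.
    """

    model: str
    params: dict
    habitats: dict = field(default_factory=dict)
    migration: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    pde: dict = field(default_factory=dict)
    experiment: dict | None = None
    note: str = ""

    def __post_init__(self):
        if self.model not in _MODELS:
            raise SchemaError(f"model: must be one of {sorted(_MODELS)}, got {self.model!r}")
        if self.model in ("model1", "model2") and self.habitats:
            _reject_unknown(self.habitats, _HABITAT_KEYS, "habitats")
            given = [k for k in ("K", "d") if self.habitats.get(k) is not None]
            if len(given) != 1:
                raise SchemaError(
                    "habitats: supply exactly one of K (capacities) or d (death rates); "
                    f"got {given or 'neither'} — mixing them silently changes the "
                    "uninfected equilibrium"
                )
        if self.migration:
            _reject_unknown(self.migration, _MIGRATION_KEYS, "migration")
            has_matrix = self.migration.get("matrix") is not None
            has_scalar = self.migration.get("m") is not None
            has_kernel = self.migration.get("kernel") is not None
            if has_kernel:
                _reject_unknown(self.migration["kernel"], _KERNEL_KEYS, "migration.kernel")
                geo = [k for k in ("distances", "positions") if self.migration.get(k) is not None]
                if len(geo) != 1 and not (has_matrix or has_scalar):
                    raise SchemaError(
                        "migration: a kernel needs exactly one of distances or positions"
                    )
            if has_matrix and has_scalar:
                raise SchemaError("migration: give either m (uniform) or matrix, not both")
            if (has_matrix or has_scalar) and has_kernel:
                warnings.warn(
                    "migration: both an explicit coefficient and a kernel were given; "
                    "the explicit matrix/scalar wins",
                    UserWarning,
                    stacklevel=2,
                )
            if not (has_matrix or has_scalar or has_kernel):
                raise SchemaError("migration: one of m, matrix, or kernel is required")
        if self.pde:
            _reject_unknown(self.pde, _PDE_KEYS, "pde")
        # validate model parameters eagerly so errors surface at load time
        if self.model in ("model1", "pde"):
            p = self.model1_params()
            violations = validate_params(p)
            if violations:
                raise SchemaError("params: constraints violated: " + "; ".join(violations))
        elif self.model == "model2":
            self.model2_params()

    # ---- materializers -------------------------------------------------

    def model1_params(self) -> Model1Params:
        p = dict(self.params)
        if "d" not in p:
            # density-dependent death rate comes from the habitat block
            p["d"] = 1.0  # placeholder magnitude; per-habitat d_j governs dynamics
            if self.habitats.get("d") is not None:
                p["d"] = float(np.min(np.atleast_1d(self.habitats["d"])))
            elif self.habitats.get("K") is not None:
                p["d"] = (p["b_U"] - p["delta_U"]) / float(np.max(np.atleast_1d(self.habitats["K"])))
        try:
            return Model1Params(**p)
        except TypeError as exc:
            raise SchemaError(f"params: {exc}") from exc

    def model2_params(self) -> Model2Params:
        try:
            return Model2Params(**self.params)
        except TypeError as exc:
            raise SchemaError(f"params: {exc}") from exc

    def n_habitats(self) -> int:
        for key in ("K", "d"):
            if self.habitats.get(key) is not None:
                return len(np.atleast_1d(self.habitats[key]))
        raise SchemaError("habitats: K or d is required to determine the habitat count")

    def kernel(self) -> DispersalKernel | None:
        spec = self.migration.get("kernel")
        if spec is None:
            return None
        return make_kernel(
            spec["family"],
            xi=float(spec["xi"]),
            sigma=None if spec.get("sigma") is None else float(spec["sigma"]),
            t=float(spec.get("t", 7.0)),
            q=float(spec.get("q", 0.95)),
            parameterization=spec.get("parameterization", "mrr"),
        )

    def migration_coefficients(self) -> np.ndarray:
        """Resolve the migration block to a symmetric N x N matrix."""
        N = self.n_habitats()
        if self.migration.get("matrix") is not None:
            M = np.asarray(self.migration["matrix"], dtype=float)
        elif self.migration.get("m") is not None:
            m = float(self.migration["m"])
            M = m * (np.ones((N, N)) - np.eye(N))
        else:
            kern = self.kernel()
            if kern is None:
                M = np.zeros((N, N))
            else:
                if self.migration.get("distances") is not None:
                    D = np.asarray(self.migration["distances"], dtype=float)
                else:
                    D = positions_to_distances(self.migration["positions"])
                M = migration_matrix(kern, D)
        if M.shape != (N, N):
            raise SchemaError(f"migration: matrix shape {M.shape} does not match {N} habitats")
        logger.info("resolved migration matrix:\n%s", M)
        return M

    def network(self) -> HabitatNetwork:
        p = self.model1_params()
        M = self.migration_coefficients()
        if self.habitats.get("K") is not None:
            net = HabitatNetwork(M=M, K=np.atleast_1d(self.habitats["K"]), params=p)
        else:
            net = HabitatNetwork(M=M, d=np.atleast_1d(self.habitats["d"]), params=p)
        logger.info("derived density-dependent death rates: %s", net.death_rates)
        return net

    def initial_model1(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_1d(np.asarray(self.initial.get("x", []), dtype=float))
        y = np.atleast_1d(np.asarray(self.initial.get("y", []), dtype=float))
        N = self.n_habitats()
        if x.size != N or y.size != N:
            raise SchemaError(f"initial: x and y must each list {N} habitat populations")
        return x, y

    def initial_model2(self) -> np.ndarray:
        states = np.asarray(self.initial.get("states", []), dtype=float)
        states = np.atleast_2d(states)
        N = self.n_habitats()
        if states.shape != (N, 9):
            raise SchemaError(f"initial: states must be an {N} x 9 table, got {states.shape}")
        return states

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        out = {"model": self.model, "note": self.note, "params": dict(self.params)}
        for key in ("habitats", "migration", "initial", "pde"):
            block = getattr(self, key)
            if block:
                out[key] = _plain(block)
        if self.experiment is not None:
            out["experiment"] = _plain(self.experiment)
        return out

    def content_hash(self) -> str:
        """Stable hash of the scenario content (for output provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_scenario(path) -> Scenario:
    """Load and validate a scenario YAML file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: scenario file must contain a mapping")
    _reject_unknown(raw, _TOP_KEYS, str(path))
    try:
        return Scenario(
            model=raw.get("model", ""),
            params=raw.get("params", {}) or {},
            habitats=raw.get("habitats", {}) or {},
            migration=raw.get("migration", {}) or {},
            initial=raw.get("initial", {}) or {},
            pde=raw.get("pde", {}) or {},
            experiment=raw.get("experiment"),
            note=raw.get("note", "") or "",
        )
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def save_scenario(scenario: Scenario, path) -> Path:
    """Write a scenario back to YAML (round-trips through load_scenario)."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)
    return path
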