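"""Durable shell-driven optimization sessions.

A physical optimization campaign can run for weeks; the state of record is
deliberately minimal and human-auditable:

* a YAML config (design space, constraints, optimizer settings), and
* an append-only CSV observation log
  (iteration, one column per factor, score, origin).

Everything else — the surrogate, the next suggestion — is derived state and
is reconstructed by *replaying* the log through a freshly seeded optimizer.
Because the loop is deterministic given (config, seed, told data), replay
always reproduces the same next suggestion, and a crash can never corrupt
more than the last unwritten row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .acquisition import AcquisitionSpec
from .optimizer import Optimizer
from .space import SearchSpace, ValidationError, constraint_from_dict

__all__ = ["SessionError", "load_config", "save_config", "Session"]

SCHEMA_VERSION = 1


class SessionError(RuntimeError):
    """The on-disk session is missing, corrupt, or inconsistent."""


def load_config(path) -> tuple[SearchSpace, list, dict]:
    """Read a campaign config: (space, constraints, settings).

    Settings keys: n_initial_points (int), acquisition (AcquisitionSpec),
    seed (int).  Unknown top-level keys are reported as schema violations.
    """
    path = Path(path)
    if not path.exists():
        raise SessionError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} is not a mapping")
    known = {"dimensions", "constraints", "n_initial_points", "acquisition", "seed",
             "schema_version"}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "dimensions" not in data:
        raise ValidationError("missing required key 'dimensions'")
    space = SearchSpace.from_dict({"dimensions": data["dimensions"]})
    constraints = [constraint_from_dict(c) for c in data.get("constraints", [])]
    settings = {
        "n_initial_points": int(data.get("n_initial_points", 4)),
        "acquisition": AcquisitionSpec.from_dict(data.get("acquisition", {})),
        "seed": int(data.get("seed", 0)),
    }
    return space, constraints, settings


def save_config(path, space: SearchSpace, constraints=None, settings=None) -> None:
    settings = settings or {}
    data = {
        "schema_version": SCHEMA_VERSION,
        "dimensions": space.to_dict()["dimensions"],
        "n_initial_points": int(settings.get("n_initial_points", 4)),
        "seed": int(settings.get("seed", 0)),
    }
    acq = settings.get("acquisition")
    if acq is not None:
        data["acquisition"] = acq.to_dict() if isinstance(acq, AcquisitionSpec) else dict(acq)
    if constraints:
        data["constraints"] = [c.to_dict() for c in constraints]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


class Session:
    """A campaign directory: config.yaml + observations.csv (+ pending.json)."""

    def __init__(self, directory):
        self.dir = Path(directory)
        self.config_path = self.dir / "config.yaml"
        self.log_path = self.dir / "observations.csv"
        self.pending_path = self.dir / "pending.json"

    # -- lifecycle -----------------------------------------------------------

    @classmethod
    def init(cls, directory, space, constraints=None, settings=None) -> "Session":
        session = cls(directory)
        session.dir.mkdir(parents=True, exist_ok=True)
        save_config(session.config_path, space, constraints, settings)
        if not session.log_path.exists():
            space_names = space.names
            header = ["iteration", *space_names, "score", "origin"]
            pd.DataFrame(columns=header).to_csv(session.log_path, index=False)
        return session

    def _require(self) -> None:
        if not self.config_path.exists():
            raise SessionError(f"no session at {self.dir} (missing config.yaml)")

    def load(self) -> tuple[SearchSpace, list, dict]:
        self._require()
        return load_config(self.config_path)

    # -- log -----------------------------------------------------------------

    def read_log(self, space: SearchSpace) -> list[tuple[list, float, str]]:
        """Parse the observation log into (recipe, score, origin) rows."""
        if not self.log_path.exists():
            return []
        try:
            # parse cells as text and convert with float() below: Python's
            # parser is correctly rounded, so logged recipes round-trip to the
            # exact bits that were told (replay must be bit-faithful)
            df = pd.read_csv(self.log_path, dtype=str)
        except Exception as exc:  # noqa: BLE001 - surfaced as session corruption
            raise SessionError(f"corrupt observation log {self.log_path}: {exc}")
        missing = [c for c in ["score", *space.names] if c not in df.columns]
        if missing:
            raise SessionError(
                f"corrupt observation log {self.log_path}: missing columns {missing}"
            )
        rows = []
        for line_no, rec in enumerate(df.to_dict("records"), start=2):
            try:
                x = []
                for d in space.dims:
                    v = rec[d.name]
                    x.append(v if d.kind == "categorical" else float(v))
                y = float(rec["score"])
            except (TypeError, ValueError) as exc:
                raise SessionError(
                    f"corrupt observation log {self.log_path} at line {line_no}: {exc}"
                )
            rows.append((x, y, str(rec.get("origin", "manual"))))
        return rows

    def append_observation(self, space: SearchSpace, x, y: float, origin: str) -> int:
        """Append one row; returns the new observation count."""
        rows = self.read_log(space)
        iteration = len(rows) + 1
        row = {"iteration": iteration}
        row.update({name: v for name, v in zip(space.names, x)})
        row["score"] = y
        row["origin"] = origin
        pd.DataFrame([row]).to_csv(self.log_path, mode="a", header=False, index=False)
        return iteration

    # -- replay --------------------------------------------------------------

    def replay(self) -> Optimizer:
        """Reconstruct the optimizer by telling every logged observation, in
        order, to a freshly seeded instance."""
        space, constraints, settings = self.load()
        opt = Optimizer(
            space,
            n_initial_points=settings["n_initial_points"],
            acq=settings["acquisition"],
            seed=settings["seed"],
            constraints=constraints,
        )
        for x, y, origin in self.read_log(space):
            if origin != "manual":
                # consume the matching ask so the queue and cache replay faithfully
                opt.ask()
            opt.tell(x, y, origin=origin)
        return opt

    # -- pending suggestions (bookkeeping only; replay is the truth) ----------

    def write_pending(self, recipes: list[list]) -> None:
        with open(self.pending_path, "w") as fh:
            json.dump({"pending": recipes}, fh)

    def clear_pending(self) -> None:
        if self.pending_path.exists():
            self.pending_path.unlink()
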