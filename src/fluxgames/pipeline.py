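"""End-to-end pipeline: model -> genotypes -> payoffs -> Nash -> dynamics -> landscape.

A :class:`RunConfig` fully determines a run; rerunning the same config
produces byte-identical numeric outputs.  Configs are plain JSON/YAML files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from . import fixtures as fx
from .dynamics import integrate, invade
from .errors import InputError
from .genotypes import VIABILITY_THRESHOLD
from .io import read_genotypes, read_model
from .landscape import AxisSpec, scan
from .nash import find_nash
from .payoffs import DEFAULT_DEATH_RATE, PayoffEngine

logger = logging.getLogger("fluxgames")

_FIXTURE_BUILDERS = {
    "sucrose": fx.make_sucrose_fixture,
    "two_amino_acid": fx.make_two_amino_acid_fixture,
}
_SCAN_FACTORIES = {
    "sucrose": fx.sucrose_scan_factory,
    "two_amino_acid": fx.amino_scan_factory,
}


@dataclass
class RunConfig:
    """A fully serializable description of one pipeline run."""

    fixture: Mapping | None = None        # {"kind": ..., other params}
    model: str | None = None              # path to a model file
    model_format: str | None = None
    genotypes: str | None = None          # path to genotype JSON
    order: int = 2
    death_rate: float = DEFAULT_DEATH_RATE
    viability_threshold: float = VIABILITY_THRESHOLD
    exchange_rule: str | None = None      # None -> fixture default / "net"
    medium: Mapping = field(default_factory=dict)
    nash_method: str = "ilp"
    dynamics: Mapping | None = None       # {"x0": {...}} or {"invasion": {...}}
    scan: Mapping | None = None           # {"axis1": {...}, "axis2": {...}}
    out_dir: str = "fluxgames_run"
    log_level: str = "INFO"

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if (self.fixture is None) == (self.model is None):
            raise InputError("config must set exactly one of 'fixture' or 'model'")
        if self.fixture is not None:
            kind = dict(self.fixture).get("kind")
            if kind not in _FIXTURE_BUILDERS:
                raise InputError(f"unknown fixture kind {kind!r}")
        else:
            if not Path(self.model).exists():
                raise InputError(f"model path {self.model!r} does not exist")
            if self.genotypes is None:
                raise InputError("a model run needs a 'genotypes' path")
            if not Path(self.genotypes).exists():
                raise InputError(f"genotypes path {self.genotypes!r} does not exist")
            if self.scan is not None:
                raise InputError("parameter scans require a fixture-based config")
        if self.order < 2:
            raise InputError("order must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


def _axis_from_spec(spec: Mapping) -> AxisSpec:
    spec = dict(spec)
    name = spec["name"]
    if "values" in spec:
        return AxisSpec(name, spec["values"])
    return AxisSpec.linspace(name, spec["lo"], spec["hi"], int(spec.get("n", 21)))


def _build_system(config: RunConfig):
    if config.fixture is not None:
        params = dict(config.fixture)
        kind = params.pop("kind")
        system = _FIXTURE_BUILDERS[kind](**params)
        if config.exchange_rule is not None or config.medium:
            system = fx.GameSystem(
                model=system.model,
                genotypes=system.genotypes,
                exchange_rule=config.exchange_rule or system.exchange_rule,
                medium={**system.medium, **config.medium},
                producer=system.producer,
                nonproducer=system.nonproducer,
                full_producer=system.full_producer,
                death_rate=config.death_rate,
                viability_threshold=config.viability_threshold,
            )
        return system
    model = read_model(config.model, config.model_format)
    genotypes = read_genotypes(config.genotypes, model)
    return fx.GameSystem(
        model=model,
        genotypes=tuple(genotypes),
        exchange_rule=config.exchange_rule or "net",
        medium=config.medium,
        death_rate=config.death_rate,
        viability_threshold=config.viability_threshold,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage, writing artifacts under ``config.out_dir``.

    Returns a map of stage name -> written path.  Stage failures raise with
    the stage name (and grid cell, for scans) in the message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    artifacts: dict = {}
    try:
        config.save(out / "config.json")
        artifacts["config"] = str(out / "config.json")

        t0 = time.perf_counter()
        system = _build_system(config)
        engine = PayoffEngine(
            model=system.model,
            death_rate=config.death_rate,
            viability_threshold=config.viability_threshold,
            exchange_rule=system.exchange_rule,
            medium=system.medium,
        )
        tensor = engine.build_payoff_tensor(list(system.genotypes), order=config.order)
        tensor.to_tsv(out / "payoffs.tsv")
        tensor.to_json(out / "payoffs.json")
        artifacts["payoffs"] = str(out / "payoffs.tsv")
        logger.info("payoff stage done in %.3fs", time.perf_counter() - t0)

        nash = find_nash(tensor, method=config.nash_method)
        (out / "nash.json").write_text(
            json.dumps(
                {
                    "method": nash.method,
                    "equilibria": [list(p) for p in nash.equilibria],
                    "profile_payoffs": {
                        "|".join(p): list(tensor.profile_payoffs(p))
                        for p in nash.equilibria
                    },
                },
                indent=1,
            )
        )
        artifacts["nash"] = str(out / "nash.json")
        logger.info("nash stage: %d equilibria", len(nash.equilibria))

        if config.dynamics is not None:
            dyn = dict(config.dynamics)
            t_max = float(dyn.get("t_max", 1000.0))
            if "invasion" in dyn:
                inv = dict(dyn["invasion"])
                traj = invade(
                    inv["residents"],
                    inv["invaders"],
                    float(inv.get("fraction", 0.01)),
                    tensor,
                    t_max=t_max,
                )
            else:
                x0_map = dyn.get("x0")
                if x0_map is None:
                    x0 = [1.0 / len(tensor.players)] * len(tensor.players)
                else:
                    x0 = [float(x0_map.get(p, 0.0)) for p in tensor.players]
                traj = integrate(x0, tensor, t_max=t_max)
            traj.to_dataframe().to_csv(out / "trajectory.csv", index=False)
            artifacts["trajectory"] = str(out / "trajectory.csv")
            logger.info("dynamics stage: converged=%s", traj.converged)

        if config.scan is not None:
            spec = dict(config.scan)
            kind = dict(config.fixture)["kind"]
            factory_kwargs = dict(spec.get("factory_params", {}))
            factory = _SCAN_FACTORIES[kind](**factory_kwargs)
            landscape = scan(
                factory,
                _axis_from_spec(spec["axis1"]),
                _axis_from_spec(spec["axis2"]),
                order=config.order,
                method=config.nash_method,
            )
            landscape.to_tsv(out / "landscape.tsv")
            artifacts["landscape"] = str(out / "landscape.tsv")
            logger.info("scan stage: %s cells", len(landscape.cells))
    finally:
        logger.removeHandler(handler)
        handler.close()
    artifacts["log"] = str(out / "run.log")
    return artifacts
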