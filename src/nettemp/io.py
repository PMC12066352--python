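"""CSV readers/writers, design configs and result serialization.

Data interchange is plain CSV: either one LONG file with ``id, wave, age,
item_*`` columns or one WIDE file per wave.  Cohort designs round-trip
through YAML/JSON configs.  Results are written as JSON (fits), CSV tables
(selection, trajectory, edge lists) and a plain-text run log, collected in a
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import MultigroupFit
from .ising import Encoding
from .panel import BinaryPanel
from .simulate import CohortDesign, Wave

logger = logging.getLogger("nettemp")

FLOAT_FMT = "%.10g"  # 10 significant digits in all numeric CSV output


@dataclass
class RunConfig:
    """Knobs of a full pipeline run."""

    data: str | None = None
    encoding: Encoding = Encoding.PM1
    enumeration_limit: int = 20
    sparse_alpha: float = 0.01
    bootstrap_B: int = 1000  # matches the 1,000-replicate convention
    seed: int = 0
    missing_policy: str = "error"  # or "listwise"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.bootstrap_B < 0:
            raise ValueError("bootstrap_B must be >= 0")
        if self.missing_policy not in ("error", "listwise"):
            raise ValueError("missing policy must be 'error' or 'listwise'")


def recode_likert(values: np.ndarray, encoding: Encoding) -> np.ndarray:
    """Binarize a 3-level (0/1/2) item: 'sometimes' counts as present."""
    v = np.asarray(values, dtype=float)
    ok = np.isin(v[np.isfinite(v)], [0.0, 1.0, 2.0])
    if not ok.all():
        raise ValueError("Likert recode expects values in {0, 1, 2}")
    lo, hi = encoding.alphabet
    return np.where(np.isnan(v), np.nan, np.where(v >= 1, hi, lo))


def _validate_alphabet(df: pd.DataFrame, items: list[str],
                       encoding: Encoding) -> None:
    vals = df[items].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    bad = sorted(set(np.unique(finite)) - set(encoding.alphabet))
    if bad:
        raise ValueError(
            f"value {bad[0]:g} is outside the {encoding.value} alphabet "
            f"{sorted(encoding.alphabet)}; check --encoding"
        )


def _apply_policy(df: pd.DataFrame, items: list[str], policy: str,
                  wave_label) -> pd.DataFrame:
    missing = df[items].isna()
    if not missing.to_numpy().any():
        return df
    if policy == "error":
        r, c = np.argwhere(missing.to_numpy())[0]
        raise ValueError(
            f"missing cell at wave {wave_label}, row {df.index[r]}, "
            f"item {items[c]}; use policy='listwise' to drop incomplete rows"
        )
    keep = ~missing.any(axis=1)
    dropped = int((~keep).sum())
    logger.info("wave %s: dropped %d incomplete rows (listwise)",
                wave_label, dropped)
    out = df[keep]
    if out.empty:
        raise ValueError(f"wave {wave_label} empty after listwise deletion")
    return out


def read_symptom_csv(path: str | list[str], layout: str = "long",
                     encoding: Encoding = Encoding.PM1,
                     policy: str = "error",
                     likert: bool = False) -> list[BinaryPanel]:
    """Read symptom panels from LONG or WIDE-per-wave CSV files.

    LONG layout is one file with columns ``id, wave, age, item_*``; WIDE is
    a list of per-wave files, each with an ``age`` column (constant within
    file) and item columns.  Waves are ordered by ascending age.  ``likert``
    first recodes 3-level items (0/1/2) to binary with 'sometimes' counted
    as present.
    """
    encoding = Encoding(encoding)
    if layout == "long":
        df = pd.read_csv(path)
        required = {"id", "wave", "age"}
        if not required <= set(df.columns):
            raise ValueError(f"LONG layout needs columns {sorted(required)}")
        items = [c for c in df.columns if c not in ("id", "wave", "age")]
        frames = [(float(sub["age"].iloc[0]), sub)
                  for _, sub in df.groupby("wave", sort=True)]
    elif layout == "wide":
        paths = [path] if isinstance(path, str) else list(path)
        frames = []
        items = None
        for fp in paths:
            sub = pd.read_csv(fp)
            if "age" not in sub.columns:
                raise ValueError(f"{fp}: WIDE layout needs an 'age' column")
            cur = [c for c in sub.columns if c not in ("id", "age")]
            if items is None:
                items = cur
            elif cur != items:
                raise ValueError("inconsistent item sets across wave files")
            frames.append((float(sub["age"].iloc[0]), sub))
    else:
        raise ValueError("layout must be 'long' or 'wide'")
    if not items:
        raise ValueError("no item columns found")
    frames.sort(key=lambda t: t[0])
    panels = []
    for g, (age, sub) in enumerate(frames):
        sub = sub.copy()
        if likert:
            sub[items] = recode_likert(sub[items].to_numpy(), encoding)
        _validate_alphabet(sub, items, encoding)
        sub = _apply_policy(sub, items, policy, wave_label=g + 1)
        panels.append(BinaryPanel(sub[items].to_numpy(dtype=float),
                                  items, age=age, wave_index=g,
                                  encoding=encoding))
    return panels


def panels_to_long_frame(panels: list[BinaryPanel]) -> pd.DataFrame:
    rows = []
    next_id = 0
    for g, pan in enumerate(panels):
        df = pd.DataFrame(pan.values, columns=pan.item_names)
        df.insert(0, "age", pan.age)
        df.insert(0, "wave", g + 1)
        df.insert(0, "id", np.arange(next_id, next_id + pan.n))
        next_id += pan.n
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def write_long_csv(panels: list[BinaryPanel], path: str) -> None:
    panels_to_long_frame(panels).to_csv(path, index=False,
                                        float_format=FLOAT_FMT)


def design_to_dict(design: CohortDesign) -> dict:
    return dict(p=design.p, encoding=design.encoding.value, seed=design.seed,
                omega=[[float(v) for v in row] for row in design.omega],
                waves=[dict(age=float(w.age), n=int(w.n),
                            tau=[float(t) for t in w.tau],
                            beta=float(w.beta)) for w in design.waves])


def design_from_dict(d: dict) -> CohortDesign:
    omega = d["omega"]
    if isinstance(omega, str):  # path to a CSV matrix
        omega = pd.read_csv(omega, header=None).to_numpy(dtype=float)
    waves = [Wave(age=w["age"], n=w["n"], tau=np.asarray(w["tau"]),
                  beta=w["beta"]) for w in d["waves"]]
    return CohortDesign(p=int(d["p"]), omega=np.asarray(omega, dtype=float),
                        waves=waves,
                        encoding=Encoding(d.get("encoding", "pm1")),
                        seed=int(d.get("seed", 0)))


def read_design(path: str) -> CohortDesign:
    text = Path(path).read_text()
    d = (json.loads(text) if path.endswith(".json") else yaml.safe_load(text))
    return design_from_dict(d)


def write_design(design: CohortDesign, path: str) -> None:
    d = design_to_dict(design)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def fit_to_dict(fit: MultigroupFit) -> dict:
    """JSON-serializable snapshot of a multigroup fit."""
    return dict(
        spec=dict(constraint_level=fit.spec.constraint_level.value,
                  structure=fit.spec.structure.value,
                  sparse_alpha=fit.spec.sparse_alpha,
                  edge_mask=[bool(b) for b in fit.edge_mask]),
        groups=[dict(age=fit.ages[g],
                     beta=float(p.beta),
                     tau=[float(t) for t in p.tau],
                     omega=[[float(v) for v in row] for row in p.omega])
                for g, p in enumerate(fit.groups)],
        loglik=fit.loglik, k=fit.k, n_per_group=fit.n_per_group,
        n_total=fit.n_total,
        se=dict(zip(fit.free_names,
                    [float(s) for s in fit.se])) if fit.se is not None
        else None,
        converged=bool(fit.converged), iterations=int(fit.iterations),
        gradient_norm=float(fit.gradient_norm),
        item_names=fit.item_names,
    )


def edge_list_frame(fit: MultigroupFit, group: int = 0) -> pd.DataFrame:
    om = fit.groups[group].omega
    iu, ju = np.triu_indices(om.shape[0], k=1)
    return pd.DataFrame(dict(i=iu + 1, j=ju + 1, weight=om[iu, ju]))


def _fingerprint(panels: list[BinaryPanel]) -> str:
    h = hashlib.sha256()
    for pan in panels:
        h.update(np.ascontiguousarray(pan.values).tobytes())
        h.update(str(pan.age).encode())
    return h.hexdigest()[:16]


def write_results(outputs: dict, out_dir: str,
                  config: RunConfig | None = None,
                  panels: list[BinaryPanel] | None = None) -> dict:
    """Write every artifact in ``outputs`` and return a manifest.

    Recognized keys: ``fit`` / ``fits`` (MultigroupFit), ``selection``
    (DataFrame), ``trajectory`` (TemperatureTrajectory), ``bootstrap``
    (BootstrapResult), plus any DataFrame under its own name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def put(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest[name] = str(path)

    for key, val in outputs.items():
        if isinstance(val, MultigroupFit):
            put(f"{key}.json", lambda p, v=val: Path(p).write_text(
                json.dumps(fit_to_dict(v), indent=2)))
            put(f"{key}_edges.csv", lambda p, v=val: edge_list_frame(v)
                .to_csv(p, index=False, float_format=FLOAT_FMT))
        elif hasattr(val, "frame"):  # TemperatureTrajectory
            put(f"{key}.csv", lambda p, v=val: v.frame.to_csv(
                p, index=False, float_format=FLOAT_FMT))
        elif isinstance(val, pd.DataFrame):
            put(f"{key}.csv", lambda p, v=val: v.to_csv(
                p, index=False, float_format=FLOAT_FMT))
        elif isinstance(val, dict):
            put(f"{key}.json", lambda p, v=val: Path(p).write_text(
                json.dumps(v, indent=2, default=float)))
        else:
            raise TypeError(f"cannot serialize output {key!r} of type "
                            f"{type(val).__name__}")

    log_lines = ["nettemp run log"]
    if config is not None:
        log_lines.append(f"seed: {config.seed}")
        log_lines.append(f"encoding: {config.encoding.value}")
        log_lines.append(f"sparse_alpha: {config.sparse_alpha}")
        log_lines.append(f"bootstrap_B: {config.bootstrap_B}")
        cfg_hash = hashlib.sha256(
            json.dumps(vars(config), default=str,
                       sort_keys=True).encode()).hexdigest()[:16]
        log_lines.append(f"config_hash: {cfg_hash}")
    if panels is not None:
        log_lines.append(f"data_fingerprint: {_fingerprint(panels)}")
        log_lines.append(
            "waves: " + ", ".join(f"n={p.n}@age{p.age:g}" for p in panels))
    put("run.log", lambda p: Path(p).write_text("\n".join(log_lines) + "\n"))
    put("manifest.json", lambda p: Path(p).write_text(
        json.dumps({k: v for k, v in manifest.items()
                    if k != "manifest.json"}, indent=2)))
    return manifest
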