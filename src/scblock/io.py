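"""Configuration files and design-table serialisation.

CSV is the interchange format for design tables (the column layout
mirrors the operating-characteristics tables: one row per realisation
with r, N_arm, N, ESS under both rate pairs, error rates and thresholds);
JSON/YAML hold single configurations and single designs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .design import BlockDesign, DesignContext
from .operating import chars_to_row, operating_characteristics
from .search import AdmissibleSet, SearchConfig

_CONTEXT_KEYS = ("p0", "p1", "alpha", "beta")
_DEFAULTS = {"max_n": 120, "theta_e_min": 0.7, "max_combos": 10**6}

TABLE_COLUMNS = [
    "design_type", "label", "r", "N_arm", "N", "B",
    "ESS00", "ESS01", "alpha_star", "power", "theta_F", "theta_E", "min_stop",
]


def read_config(path: str | Path) -> tuple[DesignContext, SearchConfig]:
    """Read a YAML or JSON search configuration.

    Required keys: p0, p1, alpha, beta, B.  Optional keys (with their
    defaults): max_n (120), theta_f_max (p1), theta_e_min (0.7),
    max_combos (10^6), r_values, n_values.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    missing = [k for k in (*_CONTEXT_KEYS, "B") if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing required key(s): {', '.join(missing)}")
    context = DesignContext(**{k: raw[k] for k in _CONTEXT_KEYS})
    cfg = SearchConfig(
        block=raw["B"],
        max_n=raw.get("max_n", _DEFAULTS["max_n"]),
        r_values=tuple(raw["r_values"]) if "r_values" in raw else None,
        n_values=tuple(raw["n_values"]) if "n_values" in raw else None,
        theta_f_max=raw.get("theta_f_max"),  # None -> p1 at search time
        theta_e_min=raw.get("theta_e_min", _DEFAULTS["theta_e_min"]),
        max_combos=raw.get("max_combos", _DEFAULTS["max_combos"]),
    )
    return context, cfg


def write_config(context: DesignContext, cfg: SearchConfig, path: str | Path) -> None:
    path = Path(path)
    data = {
        "p0": context.p0, "p1": context.p1,
        "alpha": context.alpha, "beta": context.beta,
        "B": cfg.block, "max_n": cfg.max_n,
        "theta_e_min": cfg.theta_e_min, "max_combos": cfg.max_combos,
    }
    if cfg.theta_f_max is not None:
        data["theta_f_max"] = cfg.theta_f_max
    if cfg.r_values is not None:
        data["r_values"] = list(cfg.r_values)
    if cfg.n_values is not None:
        data["n_values"] = list(cfg.n_values)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def design_to_json(design: BlockDesign, path: str | Path) -> None:
    ctx = design.context
    Path(path).write_text(json.dumps({
        "r": design.r, "N": design.n_total, "B": design.block,
        "theta_f": design.theta_f, "theta_e": design.theta_e,
        "p0": ctx.p0, "p1": ctx.p1, "alpha": ctx.alpha, "beta": ctx.beta,
    }, indent=2))


def design_from_json(path: str | Path) -> BlockDesign:
    d = json.loads(Path(path).read_text())
    return BlockDesign(
        r=d["r"], n_total=d["N"], block=d["B"],
        theta_f=d["theta_f"], theta_e=d["theta_e"],
        context=DesignContext(p0=d["p0"], p1=d["p1"], alpha=d["alpha"], beta=d["beta"]),
    )


def admissible_to_frame(adm: AdmissibleSet, design_type: str = "block") -> pd.DataFrame:
    """Flatten an admissible set to the standard table layout."""
    idx_labels = {i: [] for i in range(len(adm))}
    for tag, i in adm.labels.items():
        idx_labels[i].append(tag)
    rows = []
    for i, (d, c) in enumerate(adm.designs):
        row = {"design_type": design_type, "label": "|".join(idx_labels[i])}
        row.update(chars_to_row(d, c))
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_design_table(adm: AdmissibleSet, path: str | Path,
                       design_type: str = "block") -> None:
    admissible_to_frame(adm, design_type).to_csv(path, index=False)


def read_design_table(path: str | Path, context: DesignContext) -> AdmissibleSet:
    """Rebuild an admissible set from CSV, re-deriving the characteristics.

    The stored rows carry the design parameters; the operating
    characteristics are recomputed exactly, so a round trip is lossless up
    to the printed precision of the CSV floats.
    """
    df = pd.read_csv(path)
    designs = []
    labels: dict[str, int] = {}
    for i, row in df.iterrows():
        d = BlockDesign(
            r=int(row["r"]), n_total=int(row["N"]), block=int(row["B"]),
            theta_f=float(row["theta_F"]), theta_e=float(row["theta_E"]),
            context=context,
        )
        designs.append((d, operating_characteristics(d)))
        if isinstance(row.get("label"), str) and row["label"]:
            for tag in row["label"].split("|"):
                labels[tag] = int(i)
    return AdmissibleSet(context=context, designs=designs, labels=labels)
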