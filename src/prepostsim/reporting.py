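"""Configuration files, result serialization, and report rendering.

The config file is a flat YAML mapping whose keys mirror
:class:`prepostsim.study.StudyConfig`; unspecified keys fall back to the
default grids (n = 50..500, reliability .60/.70/.80/.90, 1000 replications).
Results are stored as one tidy CSV at full precision; rounding happens only
when a table is rendered.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .criteria import CriterionKind
from .study import StudyConfig
from .truth import CalibratedEffects

__all__ = [
    "load_config",
    "render_table",
    "RunManifest",
    "write_results",
    "read_results",
    "load_audit_frame",
]

_CONFIG_KEYS = {f.name for f in dataclasses.fields(StudyConfig)}

SEED_SCHEME = (
    "replicate seed = numpy SeedSequence with entropy "
    "(master_seed, n, round(reliability*1000), replicate index); "
    "child 0 seeds the true-score draw, child 1 the measurement noise"
)


def load_config(path) -> StudyConfig:
    """Parse a flat YAML config file into a validated StudyConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config must be a flat key-value mapping, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; valid keys are {sorted(_CONFIG_KEYS)}"
        )
    return StudyConfig(**raw)


@dataclass
class RunManifest:
    """Everything needed to reproduce a study run bit-identically."""

    config: StudyConfig
    effects: CalibratedEffects
    seed_scheme: str = SEED_SCHEME
    software_version: str = ""
    started: str = ""
    finished: str = ""
    failures_per_cell: dict = dataclasses.field(default_factory=dict)

    def mark_started(self) -> None:
        self.started = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def mark_finished(self) -> None:
        self.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_json(self, path=None) -> str:
        payload = {
            "config": {
                **dataclasses.asdict(self.config),
                "criteria": [c.value for c in self.config.criteria],
            },
            "calibrated_effects": self.effects.as_dict(),
            "seed_scheme": self.seed_scheme,
            "software_version": self.software_version,
            "started": self.started,
            "finished": self.finished,
            "failures_per_cell": self.failures_per_cell,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


_TERM_LABELS = {
    "intercept": "Intercept",
    "p1": "P-I",
    "p2": "P-II",
    "pre": "Pre-test score",
    "group": "Group",
    "p1:group": "P-I x Group",
    "p2:group": "P-II x Group",
}
_TERM_ORDER = list(_TERM_LABELS)
_CRITERION_LABELS = {
    CriterionKind.POST_TEST: "Post-test score",
    CriterionKind.ABSOLUTE_CHANGE: "Absolute change score",
    CriterionKind.RELATIVE_CHANGE: "Relative change score",
    CriterionKind.RESIDUAL_SCORE: "Residual score",
}


def render_table(
    results: pd.DataFrame,
    reliability: float,
    n: int,
    markdown: bool = False,
) -> str:
    """Render one (reliability, n) slice of observed-data results.

    Layout: one block per criterion, one row per coefficient, one column
    per model, each cell showing ``M SE P`` rounded to two decimals
    (round-half-even, the Python float formatting default).
    """
    sel = results[
        (results["data_source"] == "observed")
        & (results["n"] == n)
        & (np.isclose(results["reliability"], reliability))
    ]
    if sel.empty:
        cells = (
            results[results["data_source"] == "observed"][["reliability", "n"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        available = ", ".join(f"(rel={c.reliability:g}, n={c.n})" for c in cells)
        raise ValueError(
            f"no results for reliability={reliability:g}, n={n}; available cells: "
            f"{available or 'none'}"
        )

    model_ids = sorted(sel["model_id"].unique())
    header = ["Coefficient"] + [f"Model {m} (M SE P)" for m in model_ids]
    table_rows: list[list[str]] = []

    for criterion in CriterionKind:
        block = sel[sel["criterion"] == criterion.value]
        if block.empty:
            continue
        table_rows.append([f"** {_CRITERION_LABELS[criterion]} **"] + [""] * len(model_ids))
        for term in _TERM_ORDER:
            term_rows = block[block["term"] == term]
            if term_rows.empty:
                continue
            row = [_TERM_LABELS[term]]
            for m in model_ids:
                hit = term_rows[term_rows["model_id"] == m]
                if hit.empty:
                    row.append("")
                else:
                    r = hit.iloc[0]
                    row.append(f"{r.M:.2f} {r.SE:.2f} {r.P:.2f}")
            table_rows.append(row)

    title = f"Simulation results for reliability {reliability:g}, total n = {n}"
    widths = [
        max(len(header[j]), *(len(row[j]) for row in table_rows))
        for j in range(len(header))
    ]
    if markdown:
        lines = [
            f"### {title}",
            "",
            "| " + " | ".join(header) + " |",
            "|" + "|".join("---" for _ in header) + "|",
        ]
        lines += ["| " + " | ".join(row) + " |" for row in table_rows]
    else:
        sep = "  "

        def fmt(row):
            return sep.join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()

        rule = sep.join("-" * w for w in widths)
        lines = [title, "", fmt(header), rule] + [fmt(r) for r in table_rows]
    return "\n".join(lines) + "\n"


_GROUP_CODES = {"0": 0, "1": 1, "control": 0, "experimental": 1}


@dataclass
class TabularDataset:
    """User-supplied observed data for audit-mode fitting."""

    group: np.ndarray
    pre: np.ndarray
    post: np.ndarray
    p1: np.ndarray
    p2: np.ndarray | None = None

    data_source = "observed"


def load_audit_frame(path) -> TabularDataset:
    """Read a comma-separated file with header group, pre, post, p1[, p2]."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"group", "pre", "post", "p1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"audit file is missing columns: {sorted(missing)}")
    try:
        group = np.array([_GROUP_CODES[str(v).strip().lower()] for v in df["group"]])
    except KeyError as exc:
        raise ValueError(
            f"group values must be 0/1 or control/experimental, got {exc.args[0]!r}"
        ) from None
    return TabularDataset(
        group=group,
        pre=df["pre"].to_numpy(float),
        post=df["post"].to_numpy(float),
        p1=df["p1"].to_numpy(float),
        p2=df["p2"].to_numpy(float) if "p2" in df.columns else None,
    )
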