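"""End-to-end orchestration: statements in, report bundle out.

A run produces, for the full debate and for the periods before/after the
configured split date: the thresholded adjacency matrix (CSV), a GraphML
export with coalition labels, the coalition partition (CSV), the measures
table (CSV), and — when enough statements exist — the windowed
bipolarisation series with its LOESS curve (CSV + PNG).  A YAML run log
records parameters, seed and library versions.  All randomness flows from
the single master seed.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coalitions import girvan_newman, label_coalitions
from .errors import ParameterError
from .measures import by_type_external_ratio, summarise
from .polarisation import loess_smooth, plot_series, polarisation_series
from .statements import TimeWindow, read_statements
from .transform import build_network, build_stances
from .network import read_matrix

DEFAULT_SPLIT = dt.date(2016, 1, 15)


@dataclass
class RunConfig:
    statements_path: str | None = None
    matrix_path: str | None = None
    schema_config: dict | None = None
    threshold: float = 0.4
    split_date: dt.date = DEFAULT_SPLIT
    window: int = 200
    loess_span: float = 0.3
    seed: int = 0
    out_dir: str = "discoursenet-out"
    pro_concepts: list = field(default_factory=list)

    def __post_init__(self):
        if (self.statements_path is None) == (self.matrix_path is None):
            raise ParameterError("provide exactly one of statements_path / matrix_path")
        if isinstance(self.split_date, str):
            self.split_date = dt.date.fromisoformat(self.split_date)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _analyse_network(net, out: Path, tag: str, profile=None, pro_concepts=()):
    part = girvan_newman(net)
    labels = {}
    if profile is not None and pro_concepts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = label_coalitions(part, profile, pro_concepts)
    net.write_matrix(out / f"network_{tag}.csv")
    named = {a: labels.get(cid, f"coalition {cid}") for a, cid in part.assignment.items()}
    net.write_graphml(out / f"network_{tag}.graphml", partition=named)
    with open(out / f"partition_{tag}.csv", "w") as fh:
        fh.write("actor,coalition\n")
        for a in net.nodes:
            fh.write(f"\"{a}\",\"{named.get(a, 'isolate')}\"\n")
    table = summarise(net, part)
    table.to_csv(out / f"measures_{tag}.csv", index=False)
    by_type = by_type_external_ratio(net, part)
    with open(out / f"measures_by_type_{tag}.csv", "w") as fh:
        fh.write("org_type,external_ratio\n")
        for t, v in sorted(by_type.items()):
            fh.write(f"\"{t}\",{'' if v != v else f'{v:.2f}'}\n")
    return part, table


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the complete analysis; returns a dict of produced artefacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out)}

    if cfg.matrix_path is not None:
        try:
            net = read_matrix(cfg.matrix_path)
        except Exception as e:
            raise StageError("read_matrix", e) from e
        try:
            part, table = _analyse_network(net, out, "matrix")
        except Exception as e:
            raise StageError("analyse_matrix", e) from e
        bundle["periods"] = {"matrix": {"partition": part, "measures": table}}
    else:
        try:
            sset = read_statements(cfg.statements_path, cfg.schema_config)
        except Exception as e:
            raise StageError("ingest", e) from e
        start, end = sset.date_range()
        periods = {
            "full": sset,
            "pre": sset.filter_window(TimeWindow(start, cfg.split_date))
            if start < cfg.split_date
            else None,
            "post": sset.filter_window(TimeWindow(cfg.split_date, end + dt.timedelta(days=1)))
            if cfg.split_date <= end
            else None,
        }
        bundle["periods"] = {}
        for tag, subset in periods.items():
            if subset is None or len(subset) == 0:
                continue
            try:
                net = build_network(subset, tau=cfg.threshold)
                profile = build_stances(subset)
                part, table = _analyse_network(net, out, tag, profile, cfg.pro_concepts)
            except Exception as e:
                raise StageError(f"network_{tag}", e) from e
            bundle["periods"][tag] = {"partition": part, "measures": table}
        if len(sset) >= cfg.window:
            try:
                series = polarisation_series(
                    sset, window=cfg.window, tau=cfg.threshold, seed=cfg.seed
                )
                series = loess_smooth(series, span=cfg.loess_span)
                series.to_frame().to_csv(out / "polarisation_series.csv", index=False)
                plot_series(series, path=out / "polarisation_series.png")
                bundle["series"] = series
            except Exception as e:
                raise StageError("polarisation", e) from e

    log = {
        "discoursenet_version": __version__,
        "seed": cfg.seed,
        "threshold": cfg.threshold,
        "split_date": cfg.split_date.isoformat(),
        "window": cfg.window,
        "loess_span": cfg.loess_span,
        "input": cfg.statements_path or cfg.matrix_path,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh)
    bundle["log"] = log
    return bundle
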