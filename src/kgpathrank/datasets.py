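"""Bundled reference data: published top-ranked path records.

Two drug-repurposing case studies ship with the package as plain-text path
records in the ``node--label--node`` syntax: IL-6 receptor to
hydroxychloroquine, and STAT1 to chloroquine.  They serve as parser
fixtures and as ground truth for relationship-counting conventions.
"""

from __future__ import annotations

from importlib import resources

from .errors import ParameterError
from .io import read_path_records
from .pathrank import Path

CASE_STUDIES = {
    "il6_receptor_hydroxychloroquine":
        "il6_receptor_hydroxychloroquine_paths.tsv",
    "stat1_chloroquine": "stat1_chloroquine_paths.tsv",
}


def load_case_study(name: str) -> list[tuple[int, Path, float | None]]:
    """Load one bundled case study's (declared_depth, path, score) records.

    The declared depth is the printed one; a record's actual edge count is
    ``path.depth`` (one printed depth-3 row famously carries four edges).
    """
    if name not in CASE_STUDIES:
        raise ParameterError(
            f"unknown case study {name!r}; available: {sorted(CASE_STUDIES)}"
        )
    ref = resources.files("kgpathrank.data") / CASE_STUDIES[name]
    with ref.open("r", encoding="utf-8") as fh:
        return read_path_records(fh)
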