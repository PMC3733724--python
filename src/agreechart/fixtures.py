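"""Registry of bundled example tables.

Eight classic inter-rater agreement datasets ship with the package as
plain CSV, covering 2x2 through 6x6 ordinal scales:

* ``westlund_winnipeg`` / ``westlund_new_orleans`` — multiple sclerosis
  diagnoses (certain / probable / possible / no) for two patient series,
  each classified independently by a Winnipeg and a New Orleans
  neurologist (Westlund & Kurland 1953; reviewed in Landis & Koch 1977).
* ``lrc_elderly`` / ``lrc_nonelderly`` — cause of death (CVD vs non-CVD)
  in the Lipid Research Clinics mortality follow-up, classified by an
  expert cardiologist panel (rows) and by a trained nosologist (columns),
  split at age 65.
* ``wolfe`` / ``tabar`` / ``birads`` / ``boyd`` — repeat readings of 375
  mammograms by one radiologist on four mammographic-density risk scales
  (Garrido-Estepa et al. 2010); rows = first reading, columns = second.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .tables import ContingencyTable, read_csv

__all__ = ["FIXTURES", "list_fixtures", "load_fixture", "fixture_path", "export_fixtures"]

# name -> (description, row rater, column rater)
FIXTURES: dict[str, tuple[str, str, str]] = {
    "westlund_winnipeg": (
        "Multiple sclerosis diagnosis, Winnipeg patient series (n=149, 4 categories)",
        "New Orleans neurologist",
        "Winnipeg neurologist",
    ),
    "westlund_new_orleans": (
        "Multiple sclerosis diagnosis, New Orleans patient series (n=69, 4 categories)",
        "New Orleans neurologist",
        "Winnipeg neurologist",
    ),
    "lrc_elderly": (
        "Cause of death, elderly (>=65) deaths, LRC follow-up study (n=268, 2 categories)",
        "Expert panel",
        "Nosologist",
    ),
    "lrc_nonelderly": (
        "Cause of death, non-elderly (<65) deaths, LRC follow-up study (n=155, 2 categories)",
        "Expert panel",
        "Nosologist",
    ),
    "wolfe": (
        "Mammographic density, Wolfe scale, repeat readings (n=375, 4 categories)",
        "First measure",
        "Second measure",
    ),
    "tabar": (
        "Mammographic density, Tabar scale, repeat readings (n=375, 4 categories)",
        "First measure",
        "Second measure",
    ),
    "birads": (
        "Mammographic density, BI-RADS scale, repeat readings (n=375, 4 categories)",
        "First measure",
        "Second measure",
    ),
    "boyd": (
        "Mammographic density, Boyd scale, repeat readings (n=375, 6 categories)",
        "First measure",
        "Second measure",
    ),
}


def list_fixtures() -> list[str]:
    """Names of all bundled example tables."""
    return list(FIXTURES)


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture CSV."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {list_fixtures()}")
    return Path(resources.files("agreechart").joinpath("data", f"{name}.csv"))


def load_fixture(name: str) -> ContingencyTable:
    """Load a bundled example table by name."""
    desc, row_rater, col_rater = FIXTURES[name] if name in FIXTURES else (None,) * 3
    return read_csv(fixture_path(name), row_rater=row_rater, col_rater=col_rater)


def export_fixtures(directory: str | Path) -> list[Path]:
    """Copy all fixture CSVs into ``directory``; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name in FIXTURES:
        dest = directory / f"{name}.csv"
        dest.write_text(fixture_path(name).read_text())
        written.append(dest)
    return written
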