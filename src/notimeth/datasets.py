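"""Packaged reference fixtures: the study's printed tables and a synthetic
stand-in for its per-sample hybridization matrix.

Everything here is small plain-text data shipped with the package, loaded
through the same readers as user files so the worked examples exercise the
full I/O path.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io
from .frequency import SiteFrequency
from .model import NotISite, PanelSpec, SampleMeta

__all__ = [
    "COHORT_SIZE",
    "high_frequency_sites",
    "reference_call_matrix",
    "site_frequencies",
    "six_marker_panel",
    "study_samples",
]

#: Number of paired tumor/normal hybridizations in the reference cohort.
COHORT_SIZE = 23


def _data(name: str):
    return resources.files(__package__).joinpath("data", name)


def high_frequency_sites() -> list[NotISite]:
    """The 19 NotI sites with high methylation/deletion frequency."""
    with resources.as_file(_data("high_frequency_sites.tsv")) as path:
        return io.read_sites(path)


def site_frequencies() -> list[SiteFrequency]:
    """Printed per-site MD counts of the 19 high-frequency sites (over 23)."""
    with resources.as_file(_data("high_frequency_sites.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
        sites = io.read_sites(path)
    return [
        SiteFrequency(clone_id=s.clone_id, md_count=int(c), n_samples=COHORT_SIZE, site=s)
        for s, c in zip(sites, df["md_count"])
    ]


def study_samples() -> list[SampleMeta]:
    """Clinical annotation of the 23 ccRCC and 12 pRCC samples."""
    with resources.as_file(_data("cohort_samples.tsv")) as path:
        return io.read_samples(path)


def six_marker_panel() -> PanelSpec:
    """The six-marker detection panel with its 2-of-6 decision rule."""
    with resources.as_file(_data("six_marker_panel.yaml")) as path:
        return io.read_panel(path)


def reference_call_matrix() -> pd.DataFrame:
    """Synthetic 19 x 23 per-sample call matrix of the reference cohort.

    The study's per-sample hybridization table is not printed in the text,
    so this fixture is a *synthetic reconstruction*, built deterministically
    to satisfy every published marginal constraint simultaneously: the
    per-site MD counts of the 19 high-frequency sites; exactly five samples
    (#8, 11, 16, 17, 22) carrying MD in more than 9 of the 19 sites; 18 of
    23 samples positive under the 2-of-6 marker rule (78% sensitivity); and
    MD at the cells of the bisulfite-validated sample/gene combinations.
    Cell-level detail beyond those constraints is arbitrary.
    """
    with resources.as_file(_data("cohort_calls_synthetic.tsv")) as path:
        return io.read_call_matrix(path)
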