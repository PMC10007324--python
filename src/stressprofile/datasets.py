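"""Bundled datasets."""

from importlib import resources

from .protocol import CohortTable, read_cohort_table

__all__ = ["load_reference_cohort"]


def load_reference_cohort() -> CohortTable:
    """The packaged reference cohort: pre/post RSI values for the 38
    students of the published biofeedback-assisted mindfulness study,
    transcribed at the 3-decimal precision they were reported with."""
    ref = resources.files("stressprofile").joinpath("data/reference_cohort.csv")
    with resources.as_file(ref) as path:
        return read_cohort_table(path)
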