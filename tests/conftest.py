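import pytest
from hypothesis import settings as hypothesis_settings

from pqselect.core_io import FragmentAnnotation, PSM

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("deterministic")


def make_psm(peptide: str, intensities, spectrum_id: str = "S1",
             experiment_id: str = "exp1", accessions=("P1",),
             series_cycle: str = "ybyb") -> PSM:
    """Convenience PSM with annotation intensities spread over b/y ions."""
    annotations = []
    for i, value in enumerate(intensities):
        series = series_cycle[i % len(series_cycle)]
        index = 1 + i % (len(peptide) - 1)
        annotations.append(FragmentAnnotation(series=series, index=index,
                                              charge=1 + i % 2,
                                              intensity=float(value)))
    return PSM(spectrum_id=spectrum_id, peptide_sequence=peptide,
               protein_accessions=tuple(accessions),
               experiment_id=experiment_id, annotations=tuple(annotations))


@pytest.fixture
def psm_factory():
    return make_psm
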