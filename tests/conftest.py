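import base64
import random
import struct
import zlib

import numpy as np
import pytest

from specannot import get_model, load_modification_registry
from specannot.annotate import AnnotationSettings

from hypothesis import settings as hsettings

hsettings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
hsettings.load_profile("suite")


@pytest.fixture(scope="session")
def registry():
    return load_modification_registry()


@pytest.fixture(scope="session")
def bare_model():
    return get_model("bare")


@pytest.fixture(scope="session")
def ethcd_model():
    return get_model("ethcd")


@pytest.fixture
def default_settings():
    return AnnotationSettings()


def random_sequence(rng: random.Random, n_min=5, n_max=20) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = rng.randint(n_min, n_max)
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def make_random_sequence():
    return random_sequence


def _encode_array(values, compress=False, dtype="<d"):
    raw = b"".join(struct.pack(dtype, float(v)) for v in values)
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode()


def build_mzml(spectra, compress=False) -> str:
    """Minimal but valid mzML 1.1 text for a list of (scan, mz, intensity,
    precursor_mz, charge) MS2 spectra."""
    comp_cv = (
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>'
        if compress else
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
    )
    chunks = []
    for idx, (scan, mz, inten, prec_mz, charge) in enumerate(spectra):
        mz_b64 = _encode_array(mz, compress)
        in_b64 = _encode_array(inten, compress)
        chunks.append(f"""
      <spectrum index="{idx}" id="controllerType=0 controllerNumber=1 scan={scan}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>
        <precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>
          <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{prec_mz}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
          <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{charge}"/>
        </selectedIon></selectedIonList></precursor></precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            {comp_cv}
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            {comp_cv}
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    body = "".join(chunks)
    return f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription><fileContent>
    <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum"/>
  </fileContent></fileDescription>
  <softwareList count="1"><software id="syn" version="0"/></softwareList>
  <instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>
  <dataProcessingList count="1"><dataProcessing id="dp1"><processingMethod order="1" softwareRef="syn"/></dataProcessing></dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp1">{body}
    </spectrumList>
  </run>
</mzML>
"""


@pytest.fixture
def mzml_builder():
    return build_mzml
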