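"""Bundled demo resources: keyword table, concept dictionary, lexicons.

These files are illustrative stand-ins with the shape (not the content) of
the study resources: the real paracetamol keyword list, the licensed
concept terminology and the ~2500-entry medical-product list are not
distributed.  The synthetic corpus generator and the test suite share them,
so every planted signal is expressed in the same vocabulary the detectors
load.
"""

from importlib import resources as _resources
from pathlib import Path


def path(name: str) -> Path:
    """Filesystem path of a bundled resource file."""
    return Path(_resources.files(__package__) / name)


KEYWORDS = "keywords_demo.tsv"
CONCEPTS = "concepts_demo.tsv"
DRUGS = "drugs_demo.tsv"
GENDER_LEXICON = "gender_lexicon.tsv"
INTAKE_LEXICON = "intake_lexicon.tsv"
DEPENDENCY_LEXICON = "dependency_lexicon.txt"
OVERDOSE_LEXICON = "overdose_lexicon.txt"
SMPC = "smpc_demo.tsv"
DOSE_UNITS = "dose_units_demo.tsv"
STOPWORDS = "stopwords_fr.txt"
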