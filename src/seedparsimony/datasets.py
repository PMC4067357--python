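"""Access to user-supplied study data.

The seed-morphology study matrix (390 taxa × 17 characters) is distributed
by its authors as a PDF supplement, so this package cannot bundle it.  The
supported pathway is a manual transcription into the NEXUS or delimited
dialect of :mod:`seedparsimony.io` — fidelity of the transcription is the
transcriber's responsibility.  Place it at ``data/seed_morphology_s2.nex``
(or pass an explicit path) and :func:`load_study_matrix` will read and
sanity-check it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .io import read_matrix
from .matrix import CharacterMatrix

DEFAULT_STUDY_MATRIX_PATH = Path("data") / "seed_morphology_s2.nex"

_EXPECTED_SHAPE = (390, 17)


def load_study_matrix(path: Optional[Path] = None, strict: bool = True) -> CharacterMatrix:
    """Load a transcription of the seed-morphology study matrix.

    Parameters
    ----------
    path : Path, optional
        Location of the transcription; defaults to
        ``data/seed_morphology_s2.nex`` relative to the working directory.
    strict : bool
        Check the expected 390 × 17 shape.

    Raises
    ------
    FileNotFoundError
        If no transcription is present (the matrix is only published as a
        PDF supplement and must be transcribed by hand).
    """
    path = Path(path) if path is not None else DEFAULT_STUDY_MATRIX_PATH
    if not path.exists():
        raise FileNotFoundError(
            f"study matrix transcription not found at {path}. The 390x17 "
            "seed-morphology matrix is published only as a PDF supplement; "
            "transcribe it to NEXUS or TSV (see seedparsimony.datasets) and "
            "place it at this path."
        )
    matrix = read_matrix(path)
    if strict and (matrix.n_taxa, matrix.n_characters) != _EXPECTED_SHAPE:
        raise ValueError(
            f"transcription has shape {(matrix.n_taxa, matrix.n_characters)}, "
            f"expected {_EXPECTED_SHAPE}"
        )
    return matrix
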