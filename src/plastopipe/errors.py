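"""Exception hierarchy for the plastome toolchain."""


class PlastopipeError(Exception):
    """Base class for all package errors."""


class FormatError(PlastopipeError):
    """A file violated its format contract (FASTA/FASTQ/GenBank/tbl/config)."""


class NoQuadripartite(PlastopipeError):
    """No inverted-repeat pair long enough to define the four regions."""


class AmbiguousStructure(PlastopipeError):
    """The two single-copy arcs are equal and no reference breaks the tie."""


class CandidateOverflow(PlastopipeError):
    """The assembler produced more than two candidate assemblies."""


class AssemblyNotFound(PlastopipeError):
    """No candidate assembly was found in the assembler output directory."""


class ConfigError(PlastopipeError):
    """Invalid pipeline or sample configuration."""
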