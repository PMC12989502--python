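"""Exception types shared across the pipeline."""


class SpeechDPOAEError(Exception):
    """Base class for all package-specific errors."""


class UnvoicedInputError(SpeechDPOAEError):
    """Raised when a source signal contains no voiced frames ("unvoiced input")."""


class DegenerateAmplitudeError(SpeechDPOAEError):
    """Raised when a waveform is silent where a non-zero amplitude is required."""


class NoStimulusLockError(SpeechDPOAEError):
    """Raised when the stimulus cannot be located in a recording.

    Hardware-delay estimation requires the elicitor waveforms to be present
    in the microphone signal; without that lock the recording is unusable.
    """


class FilterDesignError(SpeechDPOAEError):
    """Raised when a requested IIR filter cannot be designed or is unstable."""
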