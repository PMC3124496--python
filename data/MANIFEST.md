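# Fixture manifest

Provenance record for transcribed empirical fixtures (see
`TRANSCRIPTION.md` for the layout and checklist).

No fixtures are currently present: the supplementary DOC tables were not
available when this repository was built, so nothing has been
transcribed. Add one entry per file below as transcriptions are made.

| file | source | transcribed by / date | notes |
|------|--------|-----------------------|-------|
| _none yet_ | | | |
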