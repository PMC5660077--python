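# Stream dialect

Plain-text, line-oriented, chunk-delimited run format, following the
layout conventions of serial-crystallography stream files. A document is
a sequence of chunks; anything between chunks is ignored; unrecognised
lines *inside* a chunk are preserved verbatim and survive a round trip.

```
document   := { chunk } ;
chunk      := "----- Begin chunk -----" NL
              { header-line | raw-line }
              peak-block
              { crystal }
              "----- End chunk -----" NL ;

header-line:= "Image filename: " STRING NL
            | "Acquisition number: " INT NL
            | "wavelength_A_1 = " FLOAT NL
            | "wavelength_A_2 = " FLOAT NL ;

peak-block := "Peaks from peak search" NL
              "  fast/px slow/px intensity/ADU snr" NL
              { FLOAT FLOAT FLOAT FLOAT NL }
              "End of peak list" NL ;

crystal    := "--- Begin crystal" NL
              "Cell parameters " FLOAT*3 " A, " FLOAT*3 " deg" NL
              "colour = " STRING NL
              "wavelength_A = " FLOAT NL
              refl-block
              "--- End crystal" NL ;

refl-block := "Reflections measured after indexing" NL
              "  h k l intensity/ADU sigma/ADU fast/px slow/px" NL
              { INT INT INT FLOAT FLOAT FLOAT FLOAT NL }
              "End of reflections" NL ;
```

* Two wavelengths per chunk (one per colour); a chunk carries 0, 1 or 2
  crystal blocks — one per indexed colour, tagged by its colour label.
* The acquisition number provides the even/odd split for half-dataset
  statistics.
* Units: pixels (0-based, fractional), ADU, Angstrom, degrees.
* Parsing is a single pass; unbalanced markers raise an error naming the
  line. `tests/data/two_chunk.stream` is the reference fixture.

The equivalent HDF5 run container (`sfx2c.container`) stores the same
records in binary form (float32 tables), typically smaller than the
text stream, with a seed and configuration echo under `/config`.
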