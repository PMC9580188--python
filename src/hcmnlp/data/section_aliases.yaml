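# Header alias table: normalized section label -> header literals.
# A header is recognised when an alias starts a line and ends with ":",
# or appears fully uppercase followed by ":", or stands alone uppercase
# on its own line.  Edit freely for local report dialects.
FINDINGS:
  - FINDINGS
  - FINDING
  - REPORT
HISTORY:
  - HISTORY
  - CLINICAL HISTORY
  - INDICATION
  - CLINICAL INDICATION
  - REASON FOR EXAM
TECHNIQUE:
  - TECHNIQUE
  - PROCEDURE
  - PROTOCOL
  - COMPARISON
MEASUREMENTS:
  - MEASUREMENTS
  - MEASUREMENT
  - QUANTITATIVE DATA
  - VALUES
IMPRESSION:
  - IMPRESSION
  - CONCLUSION
  - CONCLUSIONS
  - SUMMARY
  - INTERPRETATION
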