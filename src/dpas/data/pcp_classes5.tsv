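# Default 5-class physicochemical partition backing the PCP_* composition
# features. Membership is documented here and user-overridable.
#   HB hydrophobic, HL hydrophilic, NT neutral, PC positively charged,
#   NC negatively charged.
HB	ACFILMVW
HL	NQSTY
NT	GP
PC	KRH
NC	DE
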