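53967KTOI TOI200207010000 0.000 N 5 0.11 0.10 71 65
53967KTOI TOI200207010001 0.000 N 5 0.12 0.10 70 65
53967KTOI TOI200207010002 0.000 N 4 0.12 0.11 70 64
53967KTOI TOI200207010003 0.000 N 4 0.11 0.11 69 64
53967KTOI TOI200207010004 0.000 N 5 0.10 0.10 69 64
53967KTOI TOI200207010005 0.000 N 5 0.10 0.09 68 63
53967KTOI TOI200207010006 0.000 N 6 0.09 0.09 68 63
53967KTOI TOI200207010007 0.000 N 6 0.09 0.08 67 63
53967KTOI TOI200207010008 0.000 N 5 0.08 0.08 67 62
53967KTOI TOI200207010009 0.000 N 5 0.08 0.08 66 62
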