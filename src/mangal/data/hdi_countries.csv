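country,development,n_responses
Australia,HD,4
Brazil,HD,2
Mexico,HD,2
USA,HD,1
India,LD,3
South Africa,LD,2
Kenya,LD,1
Kiribati,LD,1
Indonesia,LD,1
Sri Lanka,LD,1
Bangladesh,LD,1
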