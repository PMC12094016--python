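strain,condition,compound,value,unit,se,n
PROP,temperature-shift,cellobiose_consumed,6.8,mM,0.53,3
PROP,temperature-shift,protein_yield,93.65,ug/mL,,3
PROP,temperature-shift,duration,112,h,,3
PROP,temperature-shift,1-propanol,0.40,mM,0.02,4
PROP,temperature-shift,propionate,0.63,mM,0.03,4
PROP,temperature-shift,ethanol,9.36,mM,0.31,4
PROP,temperature-shift,acetate,6.26,mM,0.33,4
PROP,temperature-shift,acetoin,0.0,mM,,4
PROP,temperature-shift,isoamyl alcohol,0.0,mM,,4
PROP-dAdhF,temperature-shift,cellobiose_consumed,7.0,mM,0.24,3
PROP-dAdhF,temperature-shift,protein_yield,93.65,ug/mL,,3
PROP-dAdhF,temperature-shift,duration,112,h,,3
PROP-dAdhF,temperature-shift,1-propanol,0.49,mM,0.02,4
PROP-dAdhF,temperature-shift,propionate,0.90,mM,0.06,4
PROP-dAdhF,temperature-shift,ethanol,8.98,mM,0.30,4
PROP-dAdhF,temperature-shift,acetate,7.49,mM,0.23,4
PROP-dAdhF,temperature-shift,acetoin,0.0,mM,,4
PROP-dAdhF,temperature-shift,isoamyl alcohol,0.0,mM,,4
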