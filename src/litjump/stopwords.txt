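# Function words excluded from n-gram boundaries.
a
about
after
again
all
also
among
an
and
are
as
at
be
been
being
between
both
but
by
can
could
did
do
does
during
each
for
from
had
has
have
here
how
if
in
into
is
it
its
may
might
more
most
no
not
of
on
or
our
over
per
should
so
such
than
that
the
their
then
there
these
they
this
those
through
to
under
until
upon
was
we
were
what
when
where
which
while
will
with
within
without
would
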